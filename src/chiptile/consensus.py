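"""Detector intersection, cross-replicate merging, and 250 bp trimming.

Within each replicate the chi-square-scan and HMM regions are intersected
(only intervals flagged by both detectors count as true signal). The
per-replicate region sets are then coalesced by single-linkage clustering
of midpoints: members less than 125 bp apart chain into one cluster, and
clusters supported by at least two distinct replicates become consensus
binding sites, trimmed to a uniform 250 bp around the merged midpoint.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Peak, Region

logger = logging.getLogger(__name__)


@dataclass
class MergeParams:
    max_midpoint_distance_bp: int = 125
    min_replicate_support: int = 2
    trimmed_width_bp: int = 250

    def __post_init__(self) -> None:
        if min(self.max_midpoint_distance_bp, self.min_replicate_support,
               self.trimmed_width_bp) <= 0:
            raise ValueError("all merge parameters must be > 0")


def intersect_detectors(chisq_regions: list[Region],
                        hmm_regions: list[Region]) -> list[Region]:
    """Base-pair intersections of overlapping region pairs from the two
    detectors (>= 1 bp overlap); score = max of the two members' scores.
    Regions called by only one detector are dropped."""
    by_chrom: dict[str, tuple[list[Region], list[Region]]] = {}
    for r in chisq_regions:
        by_chrom.setdefault(r.chromosome, ([], []))[0].append(r)
    for r in hmm_regions:
        by_chrom.setdefault(r.chromosome, ([], []))[1].append(r)
    out: list[Region] = []
    for chrom in sorted(by_chrom):
        a_list, b_list = by_chrom[chrom]
        a_list.sort(key=lambda r: r.start)
        b_list.sort(key=lambda r: r.start)
        j = 0
        for a in a_list:
            while j < len(b_list) and b_list[j].end < a.start:
                j += 1
            k = j
            while k < len(b_list) and b_list[k].start <= a.end:
                b = b_list[k]
                out.append(
                    Region(
                        chromosome=chrom,
                        start=max(a.start, b.start),
                        end=min(a.end, b.end),
                        score=max(a.score, b.score),
                        source="intersect",
                        replicate=a.replicate if a.replicate is not None else b.replicate,
                    )
                )
                k += 1
    out.sort(key=lambda r: (r.chromosome, r.start, r.end))
    return out


def _single_linkage_clusters(midpoints: np.ndarray, threshold: int) -> list[np.ndarray]:
    """1-D single linkage: sorted midpoints chain while adjacent gaps are
    strictly below the threshold."""
    order = np.argsort(midpoints, kind="stable")
    clusters: list[np.ndarray] = []
    current = [order[0]]
    for prev, nxt in zip(order[:-1], order[1:]):
        if midpoints[nxt] - midpoints[prev] < threshold:
            current.append(nxt)
        else:
            clusters.append(np.array(current))
            current = [nxt]
    clusters.append(np.array(current))
    return clusters


def merge_replicates(replicate_regions: list[list[Region]],
                     params: MergeParams | None = None) -> list[Peak]:
    """Coalesce per-replicate regions into consensus 250 bp peaks.

    Midpoints on each chromosome are clustered by single linkage with
    linkage threshold < max_midpoint_distance_bp; clusters carrying at
    least min_replicate_support distinct replicates become peaks. The
    merged midpoint is the floor of the mean member midpoint. If one
    replicate contributes two members to a cluster, only the member
    nearest the cluster mean is kept (logged).
    """
    params = params or MergeParams()
    if len(replicate_regions) < 2:
        raise ValueError("merging requires >= 2 replicate region lists")
    members: dict[str, list[tuple[int, int, float]]] = {}  # chrom -> (mid, rep, score)
    for rep_id, regions in enumerate(replicate_regions):
        for r in regions:
            members.setdefault(r.chromosome, []).append((r.midpoint, rep_id, r.score))

    peaks: list[Peak] = []
    for chrom in sorted(members):
        mids = np.array([m for m, _, _ in members[chrom]])
        reps = np.array([rep for _, rep, _ in members[chrom]])
        scores = np.array([s for _, _, s in members[chrom]])
        for idx in _single_linkage_clusters(mids, params.max_midpoint_distance_bp):
            c_mids, c_reps, c_scores = mids[idx], reps[idx], scores[idx]
            # one member per replicate: keep the one nearest the cluster mean
            mean0 = c_mids.mean()
            keep = []
            for rep in np.unique(c_reps):
                owned = np.where(c_reps == rep)[0]
                if len(owned) > 1:
                    logger.info(
                        "replicate %d contributes %d members to a cluster at "
                        "%s:%d; keeping the nearest", rep, len(owned), chrom, int(mean0)
                    )
                    owned = owned[[int(np.argmin(np.abs(c_mids[owned] - mean0)))]]
                keep.append(owned[0])
            keep = np.array(keep)
            support = len(np.unique(c_reps[keep]))
            if support < params.min_replicate_support:
                continue
            midpoint = int(np.floor(c_mids[keep].mean()))
            peak = trim_to_width(
                Peak(chrom, max(1, midpoint), max(1, midpoint), midpoint=midpoint,
                     support=support, score=float(c_scores[keep].min())),
                params.trimmed_width_bp,
            )
            peaks.append(peak)
    peaks.sort(key=lambda p: (p.chromosome, p.start))
    for i, p in enumerate(peaks, 1):
        p.name = f"peak_{i:04d}"
    return peaks


def trim_to_width(peak: Peak, width: int = 250) -> Peak:
    """Extend or truncate a peak to a uniform width around its midpoint.

    start = midpoint - (width/2 - 1), end = midpoint + width/2, so the span
    is exactly ``width`` positions (1-based inclusive) and re-deriving the
    midpoint by floor division returns the original midpoint. A peak too
    close to the chromosome start is shifted right to fit (warned).
    """
    half = width // 2
    start = peak.midpoint - (half - 1)
    end = peak.midpoint + half
    midpoint = peak.midpoint
    if start < 1:
        warnings.warn(
            f"peak at {peak.chromosome}:{peak.midpoint} too close to chromosome "
            "start; shifting right", stacklevel=2,
        )
        shift = 1 - start
        start += shift
        end += shift
        midpoint += shift
    return Peak(peak.chromosome, start, end, midpoint=midpoint,
                support=peak.support, name=peak.name, score=peak.score)
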