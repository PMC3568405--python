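"""Sliding-window chi-square enrichment detection (ACME-style).

The detector makes no distributional assumption about the log2 ratios
beyond one-tailedness: probes are dichotomized at an upper empirical
quantile of the pooled replicate values, a fixed-bp window is centered at
every probe, and the count of above-threshold probes in the window is
tested against the genome-wide proportion with a 1-df goodness-of-fit
statistic. Windows of several sizes (default 600/800/1000 bp) are scanned
separately and combined into significant regions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ProbeTrack, Region


@dataclass
class ScanParams:
    window_sizes_bp: tuple[int, ...] = (600, 800, 1000)
    threshold_percentile: float = 0.95
    p_cutoff: float = 1e-4
    combine_rule: str = "intersection"  # intersection | union | any-k
    combine_k: int = 2  # used by any-k
    max_gap_probes: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_percentile < 1.0):
            raise ValueError("threshold_percentile must be in (0, 1)")
        if self.combine_rule not in ("intersection", "union", "any-k"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")
        if not self.window_sizes_bp:
            raise ValueError("need at least one window size")


def compute_threshold(tracks: dict[str, ProbeTrack], percentile: float) -> float:
    """Empirical quantile (linear interpolation) of pooled probe values."""
    if not tracks:
        raise ValueError("no probe tracks")
    pooled = np.concatenate([t.values for t in tracks.values()])
    if pooled.size == 0:
        raise ValueError("empty probe tracks")
    return float(np.quantile(pooled, percentile, method="linear"))


def chisq_upper_p(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """One-tailed 1-df goodness-of-fit p for k of n successes at rate p0.

    X = (k - n p0)^2 / (n p0 (1 - p0)); the one-tailed convention zeroes
    evidence when k <= n p0 (p = 1), otherwise p is the chi-square(1) upper
    tail at X. No Yates correction.
    """
    k = np.asarray(k, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    expected = n * p0
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (k - expected) ** 2 / (n * p0 * (1.0 - p0))
    p = np.where(k <= expected, 1.0, stats.chi2.sf(x, df=1))
    return np.where(n > 0, p, 1.0)


def window_chisq(track: ProbeTrack, window_bp: int, threshold: float,
                 p0: float) -> np.ndarray:
    """Per-probe one-tailed p-values for a window of window_bp centered at
    each probe position.

    For the window at probe position c, n counts probes with position in
    [c - window_bp/2, c + window_bp/2] and k those with value strictly
    above the threshold.
    """
    pos = track.positions
    if len(pos) == 0:
        return np.zeros(0)
    spacing = float(np.median(np.diff(pos))) if len(pos) > 1 else window_bp
    if window_bp < spacing:
        warnings.warn(
            f"window {window_bp} bp smaller than probe spacing {spacing:.0f} bp",
            stacklevel=2,
        )
    half = window_bp / 2.0
    above = np.cumsum(np.concatenate(([0], (track.values > threshold).astype(np.int64))))
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    n = hi - lo
    k = above[hi] - above[lo]
    return chisq_upper_p(k, n, p0)


def combine_significance(pvals: dict[int, np.ndarray], params: ScanParams) -> np.ndarray:
    """Boolean per-probe significance under the combine rule across window sizes."""
    mats = np.stack([pvals[w] < params.p_cutoff for w in sorted(pvals)])
    if params.combine_rule == "intersection":
        return mats.all(axis=0)
    if params.combine_rule == "union":
        return mats.any(axis=0)
    return mats.sum(axis=0) >= params.combine_k


def significant_regions(track: ProbeTrack, pvals: dict[int, np.ndarray],
                        params: ScanParams, replicate: int | None = None) -> list[Region]:
    """Fuse significant probes into regions.

    A probe is significant iff its p-value beats p_cutoff under the combine
    rule across window sizes; runs separated by at most max_gap_probes
    non-significant probes are fused. Each region spans the first to last
    significant probe position; its score is the minimum p over member
    probes and window sizes.
    """
    for w, p in pvals.items():
        if len(p) != len(track):
            raise ValueError(f"p-value vector for window {w} misaligned with track")
    sig = combine_significance(pvals, params)
    idx = np.where(sig)[0]
    if idx.size == 0:
        return []
    pmin = np.min(np.stack([pvals[w] for w in pvals]), axis=0)
    regions: list[Region] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > params.max_gap_probes:
            regions.append(_make_region(track, run_start, prev, pmin, replicate))
            run_start = i
        prev = i
    regions.append(_make_region(track, run_start, prev, pmin, replicate))
    return regions


def _make_region(track: ProbeTrack, i0: int, i1: int, pmin: np.ndarray,
                 replicate: int | None) -> Region:
    return Region(
        chromosome=track.chromosome,
        start=int(track.positions[i0]),
        end=int(track.positions[i1]),
        score=float(pmin[i0 : i1 + 1].min()),
        source="chisq_scan",
        replicate=replicate,
    )


def scan_replicate(tracks: dict[str, ProbeTrack], params: ScanParams,
                   replicate: int | None = None) -> list[Region]:
    """Full chi-square scan of one replicate: threshold, per-window tests,
    combine, fuse. Returns regions across all chromosomes."""
    threshold = compute_threshold(tracks, params.threshold_percentile)
    # p0 equals the upper-tail mass by construction of the empirical quantile
    p0 = 1.0 - params.threshold_percentile
    regions: list[Region] = []
    for chrom in sorted(tracks):
        track = tracks[chrom]
        pvals = {w: window_chisq(track, w, threshold, p0) for w in params.window_sizes_bp}
        regions.extend(significant_regions(track, pvals, params, replicate))
    return regions
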