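"""Peak-to-feature assignment and occupancy statistics.

A consensus peak is assigned to the annotated feature nearest its
midpoint, provided the midpoint lies within (or within 125 bp of) the
feature span; otherwise the peak is intergenic. From the assignments the
module derives the binding-site composition by feature class, the percent
of each class's features that are bound, and per-gene-family occupancy
counts (e.g. how many allelic tDNA copies of one tRNA species are bound).
"""
from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass

from .core import CLASS_PRIORITY, FeatureTable, Peak, interval_distance

logger = logging.getLogger(__name__)

INTERGENIC = "intergenic"


@dataclass
class PeakAssignment:
    peak_name: str
    chromosome: str
    midpoint: int
    feature: str  # feature name or "intergenic"
    feature_class: str  # class or "intergenic"
    distance: int  # 0 if midpoint inside the span, else bp gap to nearest edge


def assign_peaks(peaks: list[Peak], features: FeatureTable,
                 proximity_bp: int = 125) -> list[PeakAssignment]:
    """Assign every peak to at most one feature by midpoint proximity.

    Candidates are features whose span lies within ``proximity_bp`` of the
    peak midpoint (distance 0 if the midpoint falls inside). The nearest
    candidate wins; ties are broken by feature-class priority (tRNA_gene >
    snoRNA_gene > snRNA_gene > ncRNA_gene > ARS > ORF > other), then by
    name. Peaks with no candidate are intergenic.
    """
    by_chrom = features.by_chromosome()
    assignments: list[PeakAssignment] = []
    for peak in peaks:
        best = None
        for f in by_chrom.get(peak.chromosome, []):
            d = interval_distance(peak.midpoint, f.start, f.end)
            if d > proximity_bp:
                continue
            key = (d, CLASS_PRIORITY[f.feature_class], f.name)
            if best is None or key < best[0]:
                best = (key, f)
        if best is None:
            assignments.append(
                PeakAssignment(peak.name, peak.chromosome, peak.midpoint,
                               INTERGENIC, INTERGENIC, 0)
            )
        else:
            (d, _, _), f = best
            assignments.append(
                PeakAssignment(peak.name, peak.chromosome, peak.midpoint,
                               f.name, f.feature_class, d)
            )
    return assignments


def class_composition(assignments: list[PeakAssignment]) -> dict[str, float]:
    """Fraction of all peaks assigned to each feature class (incl. intergenic)."""
    if not assignments:
        raise ValueError("no peak assignments")
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.feature_class] = counts.get(a.feature_class, 0) + 1
    total = len(assignments)
    return {cls: n / total for cls, n in sorted(counts.items())}


def fraction_bound(assignments: list[PeakAssignment],
                   features: FeatureTable) -> dict[str, float]:
    """Percent of each class's features with >= 1 assigned peak.

    A feature counts once however many peaks it carries. Classes with zero
    features in the annotation are omitted (warned in the log).
    """
    bound: dict[str, set[str]] = {}
    for a in assignments:
        if a.feature != INTERGENIC:
            bound.setdefault(a.feature_class, set()).add(a.feature)
    totals = features.class_counts()
    out: dict[str, float] = {}
    for cls in sorted(set(totals) | set(bound)):
        if totals.get(cls, 0) == 0:
            logger.warning("class %s has no features in the annotation; omitted", cls)
            continue
        out[cls] = 100.0 * len(bound.get(cls, set())) / totals[cls]
    return out


def allele_occupancy(assignments: list[PeakAssignment], features: FeatureTable,
                     gene_family: str) -> tuple[int, int]:
    """(bound, total) counts over a family of features selected by a glob
    pattern on the feature name, e.g. all allelic copies of one tRNA species."""
    family = [f.name for f in features if fnmatch.fnmatch(f.name, gene_family)]
    if not family:
        raise ValueError(f"gene family pattern {gene_family!r} matches no feature")
    bound_names = {a.feature for a in assignments if a.feature != INTERGENIC}
    n_bound = sum(1 for name in family if name in bound_names)
    return n_bound, len(family)
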