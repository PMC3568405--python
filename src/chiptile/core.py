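"""Core domain types shared across the pipeline.

Coordinate convention: 1-based, inclusive on both ends, matching GFF.
A feature spanning [start, end] covers end - start + 1 bases.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Feature classes the annotator distinguishes. Order is the tie-break
#: priority used when a peak midpoint is equidistant from two features:
#: short ncRNA genes outrank ORFs so they are not shadowed by long
#: neighbouring ORFs.
FEATURE_CLASSES = (
    "tRNA_gene",
    "snoRNA_gene",
    "snRNA_gene",
    "ncRNA_gene",
    "ARS",
    "ORF",
    "other",
)

CLASS_PRIORITY = {c: i for i, c in enumerate(FEATURE_CLASSES)}


@dataclass
class ProbeTrack:
    """Ordered probe midpoints and normalized log2(IP/input) ratios for one chromosome."""

    chromosome: str
    positions: np.ndarray  # int, strictly increasing, 1-based bp
    values: np.ndarray  # float, same length

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError(
                f"{self.chromosome}: {len(self.positions)} positions vs "
                f"{len(self.values)} values"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            bad = int(self.positions[np.where(np.diff(self.positions) <= 0)[0][0] + 1])
            raise ValueError(
                f"{self.chromosome}: probe positions not strictly increasing "
                f"(at position {bad})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.chromosome}: non-finite probe values")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class Feature:
    """One annotated genomic feature (1-based inclusive span)."""

    name: str
    chromosome: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    feature_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.name}: start {self.start} > end {self.end}"
            )
        if self.feature_class not in CLASS_PRIORITY:
            raise ValueError(f"feature {self.name}: unknown class {self.feature_class}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    """Typed genomic features with unique names."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise ValueError(f"duplicate feature name: {dup}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_class(self, feature_class: str) -> "FeatureTable":
        return FeatureTable([f for f in self.features if f.feature_class == feature_class])

    def by_chromosome(self) -> dict[str, list[Feature]]:
        out: dict[str, list[Feature]] = {}
        for f in self.features:
            out.setdefault(f.chromosome, []).append(f)
        for lst in out.values():
            lst.sort(key=lambda f: (f.start, f.end, f.name))
        return out

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.feature_class] = counts.get(f.feature_class, 0) + 1
        return counts

    def subset(self, names) -> "FeatureTable":
        names = set(names)
        return FeatureTable([f for f in self.features if f.name in names])


@dataclass
class Region:
    """A genomic interval emitted by a detector or intersection stage."""

    chromosome: str
    start: int
    end: int
    score: float = 0.0
    source: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end}]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class Peak:
    """A uniform-width consensus binding site supported by >= 2 replicates."""

    chromosome: str
    start: int
    end: int
    midpoint: int
    support: int
    name: str = ""
    score: float = 0.0

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def interval_distance(point: int, start: int, end: int) -> int:
    """bp gap from a point to an inclusive interval; 0 if the point is inside."""
    if point < start:
        return start - point
    if point > end:
        return point - end
    return 0
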