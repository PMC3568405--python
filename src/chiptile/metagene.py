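"""Average occupancy profiles over scaled feature bodies with fixed flanks.

Each feature body is split into 50 equal-width bins; upstream and
downstream flanks are fixed at 250 bp and binned at the class's mean body
bin width (so flank bins are comparable in width to body bins). Probe
values falling in a bin are summed and averaged, pooled over all features
of the set, with minus-strand features reversed so every profile reads
5' -> 3' in transcription orientation. Profiles can be stratified by
transcription-rate class (high >= 15 mRNAs/hr, medium 1-15, low <= 1) or
restricted to the features called bound by the annotator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotate import INTERGENIC, PeakAssignment
from .core import FeatureTable, ProbeTrack


@dataclass
class RateClassSpec:
    """Transcription-rate class boundaries (mRNAs/hr).

    Edge ownership: rate >= high_min -> high; rate <= low_max -> low;
    everything strictly between -> medium.
    """

    high_min: float = 15.0
    low_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.low_max < self.high_min):
            raise ValueError("need 0 <= low_max < high_min")

    def classify(self, rate: float) -> str:
        if rate < 0:
            raise ValueError(f"negative transcription rate {rate}")
        if rate >= self.high_min:
            return "high"
        if rate <= self.low_max:
            return "low"
        return "medium"


@dataclass
class MetageneProfile:
    label: str
    flank_bp: int
    n_body_bins: int
    n_flank_bins: int
    bin_sums: np.ndarray
    bin_counts: np.ndarray
    n_features: int

    @property
    def n_bins(self) -> int:
        return self.n_body_bins + 2 * self.n_flank_bins

    @property
    def bin_means(self) -> np.ndarray:
        """Per-bin mean enrichment; NaN where no probe fell in the bin."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.bin_counts > 0, self.bin_sums / self.bin_counts, np.nan)

    def relative_coordinates(self) -> np.ndarray:
        """Bin centers on a -flank..0..1..+flank axis (body scaled to [0,1])."""
        nf, nb = self.n_flank_bins, self.n_body_bins
        up = -self.flank_bp * (nf - np.arange(nf) - 0.5) / nf / 1000.0
        body = (np.arange(nb) + 0.5) / nb
        down = 1.0 + self.flank_bp * (np.arange(nf) + 0.5) / nf / 1000.0
        return np.concatenate([up, body, down])

    def to_tsv(self, path) -> None:
        means = self.bin_means
        rel = self.relative_coordinates()
        with open(path, "w") as fh:
            fh.write("# label=%s n_features=%d\n" % (self.label, self.n_features))
            fh.write("bin\trel_coord\tmean\tn\n")
            for i in range(self.n_bins):
                m = "NA" if np.isnan(means[i]) else f"{means[i]:.6g}"
                fh.write(f"{i}\t{rel[i]:.4f}\t{m}\t{int(self.bin_counts[i])}\n")


def average_tracks(replicates: list[dict[str, ProbeTrack]]) -> dict[str, ProbeTrack]:
    """Probe-wise mean of replicate tracks (one enrichment surface).

    Requires identical probe positions across replicates.
    """
    if not replicates:
        raise ValueError("no replicates")
    out: dict[str, ProbeTrack] = {}
    for chrom in sorted(replicates[0]):
        pos = replicates[0][chrom].positions
        for rep in replicates[1:]:
            if chrom not in rep or not np.array_equal(rep[chrom].positions, pos):
                raise ValueError(f"replicates disagree on probe positions for {chrom}")
        mean = np.mean([rep[chrom].values for rep in replicates], axis=0)
        out[chrom] = ProbeTrack(chrom, pos.copy(), mean)
    return out


def average_profile(signal: dict[str, ProbeTrack], features: FeatureTable,
                    n_bins: int = 50, flank_bp: int = 250,
                    label: str = "") -> MetageneProfile:
    """Pooled mean profile over a feature set: 50 body bins + fixed flanks.

    Flank bin width is the mean body-bin width of the set (mean body length
    / n_bins) and the number of flank bins is max(1, round(flank_bp / that
    width)). Bin membership is by probe midpoint in half-open [lo, hi)
    bins. Features shorter than n_bins bp are skipped with a warning.
    Minus-strand features are reversed before pooling.
    """
    usable = [f for f in features if f.length >= n_bins]
    for f in features:
        if f.length < n_bins:
            warnings.warn(f"feature {f.name} shorter than {n_bins} bp; skipped",
                          stacklevel=2)
    if not usable:
        raise ValueError(f"no usable features for profile {label!r}")
    mean_len = float(np.mean([f.length for f in usable]))
    flank_bin_width = mean_len / n_bins
    n_flank = max(1, int(round(flank_bp / flank_bin_width)))
    B = n_bins + 2 * n_flank
    sums = np.zeros(B)
    counts = np.zeros(B, dtype=np.int64)

    for f in usable:
        track = signal.get(f.chromosome)
        if track is None:
            continue
        up_edges = f.start - flank_bin_width * (n_flank - np.arange(n_flank))
        body_edges = f.start + f.length * np.arange(n_bins) / n_bins
        down_edges = (f.end + 1) + flank_bin_width * np.arange(n_flank + 1)
        edges = np.concatenate([up_edges, body_edges, down_edges])
        lo = np.searchsorted(track.positions, edges[0], side="left")
        hi = np.searchsorted(track.positions, edges[-1], side="left")
        pos = track.positions[lo:hi]
        vals = track.values[lo:hi]
        # bin index for half-open [e_i, e_{i+1})
        bins = np.searchsorted(edges, pos, side="right") - 1
        ok = (bins >= 0) & (bins < B)
        bins, vals = bins[ok], vals[ok]
        if f.strand == "-":
            bins = B - 1 - bins
        np.add.at(sums, bins, vals)
        np.add.at(counts, bins, 1)

    return MetageneProfile(label=label, flank_bp=flank_bp, n_body_bins=n_bins,
                           n_flank_bins=n_flank, bin_sums=sums, bin_counts=counts,
                           n_features=len(usable))


def classify_by_rate(features: FeatureTable, rates: dict[str, float],
                     spec: RateClassSpec | None = None) -> dict[str, FeatureTable]:
    """Partition features into high/medium/low transcription-rate classes.

    Features without a rate entry go to "unclassified" rather than being
    silently dropped.
    """
    spec = spec or RateClassSpec()
    groups: dict[str, list] = {"high": [], "medium": [], "low": [], "unclassified": []}
    for f in features:
        if f.name in rates:
            groups[spec.classify(rates[f.name])].append(f)
        else:
            groups["unclassified"].append(f)
    return {k: FeatureTable(v) for k, v in groups.items()}


def bound_subset_profile(signal: dict[str, ProbeTrack], features: FeatureTable,
                         assignments: list[PeakAssignment], n_bins: int = 50,
                         flank_bp: int = 250, label: str = "bound") -> MetageneProfile:
    """Profile restricted to features carrying >= 1 assigned peak."""
    bound_names = {a.feature for a in assignments if a.feature != INTERGENIC}
    subset = features.subset(bound_names)
    if len(subset) == 0:
        raise ValueError(f"no bound features in set {label!r}")
    return average_profile(signal, subset, n_bins=n_bins, flank_bp=flank_bp, label=label)
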