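"""Synthetic yeast-like ChIP-chip datasets with planted ground truth.

The generator emulates, at miniature scale, a genome-wide location
experiment on a high-density tiling array: a multi-chromosome genome
annotated with ORFs, tDNAs, snoRNA genes and replication origins (ARSs),
~32 bp probe tiling, Gaussian background log2(IP/input) ratios, and flat
enrichment plateaus planted at the 5' ends of a configurable fraction of
features. True peaks are shared across all replicates; each replicate
additionally carries its own spurious single-replicate noise peaks, which
the >= 2-replicate consensus rule is expected to remove. The planted
intervals are recorded as ground truth so detection can be scored.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import Feature, FeatureTable, ProbeTrack

#: minimum bp between any two features (both flanks)
MIN_FEATURE_GAP_BP = 200
#: minimum bp between two planted true-peak intervals, so each recovered
#: consensus midpoint maps unambiguously to one truth interval
MIN_TRUE_PEAK_GAP_BP = 150
#: minimum bp from a noise interval to every other planted interval; keeps
#: noise peaks of different replicates un-mergeable by construction
NOISE_CLEARANCE_BP = 300


@dataclass
class SimConfig:
    """Study conditions for the miniature synthetic dataset.

    Defaults give 2 x 250 kb chromosomes tiled at 32 bp (~15,600 probes) and
    226 features. Bound fractions mirror the occupancy the analysis is meant
    to recover (10% of ORFs, 40% of tRNA genes, 35% of snoRNA genes, 25% of
    ARSs -> 44 true peaks), planted as 800 bp plateaus of amplitude 2.0 over
    a background sigma of 0.5 (amplitude/sigma = 4), with 3 replicates and
    30 single-replicate noise peaks each.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 250_000
    probe_spacing_bp: int = 32
    probe_length_bp: int = 50
    n_orfs: int = 140
    n_tdnas: int = 40
    n_snornas: int = 26
    n_arss: int = 20
    orf_length_range_bp: tuple[int, int] = (500, 2000)
    tdna_length_bp: int = 80
    snorna_length_bp: int = 150
    ars_length_bp: int = 200
    background_sd: float = 0.5
    peak_amplitude: float = 2.0
    peak_width_bp: int = 800
    bound_fraction_per_class: dict[str, float] = field(
        default_factory=lambda: {
            "ORF": 0.10,
            "tRNA_gene": 0.40,
            "snoRNA_gene": 0.35,
            "ARS": 0.25,
        }
    )
    n_replicates: int = 3
    replicate_noise_peaks: int = 30
    rate_lognormal_params: tuple[float, float] = (1.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be > 0")
        if self.n_chromosomes <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("need >= 1 chromosome of positive length")
        for name in ("n_orfs", "n_tdnas", "n_snornas", "n_arss",
                     "n_replicates", "replicate_noise_peaks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.orf_length_range_bp
        if not (0 < lo <= hi):
            raise ValueError("orf_length_range_bp must satisfy 0 < min <= max")
        for cls, frac in self.bound_fraction_per_class.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"bound fraction for {cls} must be in [0, 1]")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimTruth:
    """Planted-peak ground truth: the oracle that detection is scored against."""

    #: (chromosome, start, end, target feature name) — identical in every replicate
    true_peaks: list[tuple[str, int, int, str]]
    #: per replicate: list of (chromosome, start, end) spurious intervals
    noise_peaks: list[list[tuple[str, int, int]]]
    #: gene name -> transcription rate (mRNAs/hr)
    rates: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"true_peaks": self.true_peaks, "noise_peaks": self.noise_peaks,
                 "rates": self.rates},
                fh, indent=1,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_peaks=[tuple(t) for t in d["true_peaks"]],
            noise_peaks=[[tuple(t) for t in rep] for rep in d["noise_peaks"]],
            rates=d["rates"],
        )


# ---------------------------------------------------------------------------
# annotation


def _feature_plan(config: SimConfig, rng: np.random.Generator):
    lo, hi = config.orf_length_range_bp
    plan: list[tuple[str, str, int]] = []  # (class, name, length)
    for i in range(config.n_orfs):
        plan.append(("ORF", f"ORF_{i + 1:04d}", int(rng.integers(lo, hi + 1))))
    for i in range(config.n_tdnas):
        plan.append(("tRNA_gene", f"tDNA_{i + 1:04d}", config.tdna_length_bp))
    for i in range(config.n_snornas):
        plan.append(("snoRNA_gene", f"snoRNA_{i + 1:04d}", config.snorna_length_bp))
    for i in range(config.n_arss):
        plan.append(("ARS", f"ARS_{i + 1:04d}", config.ars_length_bp))
    return plan


def simulate_annotation(config: SimConfig) -> FeatureTable:
    """Place non-overlapping features with >= 200 bp gaps on both strands.

    Features are assigned to chromosomes by balancing total occupied span,
    then laid out left-to-right with randomized gaps. Raises a sizing error
    naming the violated constraint if a chromosome cannot hold its share.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = _feature_plan(config, rng)
    if not plan:
        return FeatureTable([])
    order = rng.permutation(len(plan))

    chroms = config.chromosome_names()
    load = {c: 0 for c in chroms}
    assigned: dict[str, list[tuple[str, str, int]]] = {c: [] for c in chroms}
    for idx in order:
        cls, name, length = plan[idx]
        target = min(chroms, key=lambda c: load[c])
        assigned[target].append((cls, name, length))
        load[target] += length + MIN_FEATURE_GAP_BP

    features: list[Feature] = []
    for chrom in chroms:
        items = assigned[chrom]
        total = sum(length for _, _, length in items)
        required = total + MIN_FEATURE_GAP_BP * (len(items) + 1)
        if required > config.chrom_length_bp:
            raise ValueError(
                f"{chrom}: {len(items)} features need {required} bp "
                f"(spans {total} + {MIN_FEATURE_GAP_BP} bp gaps) but chromosome "
                f"is {config.chrom_length_bp} bp"
            )
        slack = config.chrom_length_bp - required
        # split the slack into len(items)+1 random extra gaps
        if slack > 0 and items:
            cuts = np.sort(rng.integers(0, slack + 1, size=len(items)))
            extras = np.diff(np.concatenate(([0], cuts, [slack])))
        else:
            extras = np.zeros(len(items) + 1, dtype=int)
        pos = 1
        for i, (cls, name, length) in enumerate(items):
            pos += MIN_FEATURE_GAP_BP + int(extras[i])
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(Feature(name, chrom, pos, pos + length - 1, strand, cls))
            pos += length
    features.sort(key=lambda f: (f.chromosome, f.start))
    return FeatureTable(features)


# ---------------------------------------------------------------------------
# signal tracks


def _tss_peak_interval(f: Feature, width: int, chrom_len: int) -> tuple[int, int]:
    """Planted interval for one bound feature.

    Features shorter than the peak width (tDNAs, snoRNA genes) get the
    interval centered on the gene, which the enrichment then covers whole;
    longer features (ORFs) get it anchored at the 5' end, one quarter
    upstream and three quarters into the body.
    """
    if f.length <= width:
        mid = (f.start + f.end) // 2
        start = max(1, mid - width // 2 + 1)
        end = min(chrom_len, start + width - 1)
        return start, end
    if f.strand == "-":
        end = min(chrom_len, f.end + width // 4)
        start = max(1, end - width + 1)
    else:
        start = max(1, f.start - width // 4)
        end = min(chrom_len, start + width - 1)
    return start, end


def _gap_to_all(intervals: list[tuple[int, int]], start: int, end: int) -> int:
    gap = np.inf
    for s, e in intervals:
        if end < s:
            gap = min(gap, s - end)
        elif e < start:
            gap = min(gap, start - e)
        else:
            return 0
    return int(gap) if np.isfinite(gap) else 10**9


def probe_centers(config: SimConfig) -> np.ndarray:
    """Probe midpoint coordinates for one chromosome under the tiling design."""
    n = (config.chrom_length_bp - config.probe_length_bp) // config.probe_spacing_bp + 1
    starts = 1 + config.probe_spacing_bp * np.arange(n, dtype=np.int64)
    return starts + config.probe_length_bp // 2


def simulate_tracks(
    features: FeatureTable, config: SimConfig
) -> tuple[list[dict[str, ProbeTrack]], SimTruth]:
    """Generate per-replicate probe tracks and the planted-peak ground truth.

    Background values are i.i.d. Normal(0, background_sd); probes whose
    midpoint falls inside a true or (replicate-own) noise interval get
    peak_amplitude added. True peaks are planted at the 5' ends of a
    per-class fraction of features and are identical across replicates.
    """
    config.validate()
    if config.peak_amplitude <= 0:
        raise ValueError("peak_amplitude must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom_names = config.chromosome_names()
    by_class = {}
    for f in features:
        by_class.setdefault(f.feature_class, []).append(f)

    planted: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    true_peaks: list[tuple[str, int, int, str]] = []
    for cls in sorted(config.bound_fraction_per_class):
        frac = config.bound_fraction_per_class[cls]
        members = by_class.get(cls, [])
        n_bound = int(round(frac * len(members)))
        if n_bound == 0:
            continue
        candidates = [members[i] for i in rng.permutation(len(members))]
        chosen: list[Feature] = []
        deferred: list[Feature] = []
        for f in candidates:
            if len(chosen) == n_bound:
                break
            s, e = _tss_peak_interval(f, config.peak_width_bp, config.chrom_length_bp)
            if _gap_to_all(planted[f.chromosome], s, e) >= MIN_TRUE_PEAK_GAP_BP:
                chosen.append(f)
                planted[f.chromosome].append((s, e))
                true_peaks.append((f.chromosome, s, e, f.name))
            else:
                deferred.append(f)
        for f in deferred[: n_bound - len(chosen)]:
            s, e = _tss_peak_interval(f, config.peak_width_bp, config.chrom_length_bp)
            warnings.warn(
                f"planting a crowded peak at {f.name}; truth intervals may abut",
                stacklevel=2,
            )
            planted[f.chromosome].append((s, e))
            true_peaks.append((f.chromosome, s, e, f.name))
    true_peaks.sort()

    # replicate-specific noise intervals, kept clear of everything else so no
    # cross-replicate pair can merge
    all_planted = {c: list(planted[c]) for c in chrom_names}
    noise_peaks: list[list[tuple[str, int, int]]] = []
    width = config.peak_width_bp
    for _rep in range(config.n_replicates):
        rep_noise: list[tuple[str, int, int]] = []
        attempts = 0
        while len(rep_noise) < config.replicate_noise_peaks:
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError(
                    "could not place replicate noise peaks with the required "
                    f"{NOISE_CLEARANCE_BP} bp clearance; genome too crowded"
                )
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(1, config.chrom_length_bp - width + 1))
            end = start + width - 1
            if _gap_to_all(all_planted[chrom], start, end) >= NOISE_CLEARANCE_BP:
                rep_noise.append((chrom, start, end))
                all_planted[chrom].append((start, end))
        rep_noise.sort()
        noise_peaks.append(rep_noise)

    # per-ORF transcription rates
    mu, sigma = config.rate_lognormal_params
    orfs = sorted(f.name for f in by_class.get("ORF", []))
    rates = {name: float(rng.lognormal(mu, sigma)) for name in orfs}

    # signal tracks
    replicates: list[dict[str, ProbeTrack]] = []
    centers = {c: probe_centers(config) for c in chrom_names}
    true_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for chrom, s, e, _name in true_peaks:
        true_by_chrom[chrom].append((s, e))
    for rep in range(config.n_replicates):
        tracks: dict[str, ProbeTrack] = {}
        for chrom in chrom_names:
            pos = centers[chrom]
            values = rng.normal(0.0, config.background_sd, size=len(pos))
            bump = np.zeros(len(pos), dtype=bool)
            for s, e in true_by_chrom[chrom]:
                bump |= (pos >= s) & (pos <= e)
            for nchrom, s, e in noise_peaks[rep]:
                if nchrom == chrom:
                    bump |= (pos >= s) & (pos <= e)
            values[bump] += config.peak_amplitude
            tracks[chrom] = ProbeTrack(chrom, pos, values)
        replicates.append(tracks)

    return replicates, SimTruth(true_peaks, noise_peaks, rates)


# ---------------------------------------------------------------------------
# genome sequence with planted motif occurrences


def simulate_sequences(
    config: SimConfig,
    truth: SimTruth,
    motif_consensus: str,
    planted_fraction: float,
    seed: int,
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Uniform-random A/C/G/T genome with the motif consensus inserted into
    a fraction of the true-peak intervals.

    Returns (chromosome -> sequence, list of (chromosome, 1-based insertion
    start) for every planted occurrence).
    """
    motif_consensus = motif_consensus.upper()
    if not set(motif_consensus) <= set("ACGT"):
        raise ValueError("motif consensus must be over A/C/G/T")
    if not (0.0 <= planted_fraction <= 1.0):
        raise ValueError("planted_fraction must be in [0, 1]")
    L = len(motif_consensus)
    shortest = min((e - s + 1 for _, s, e, _ in truth.true_peaks), default=config.peak_width_bp)
    if L >= shortest:
        raise ValueError(f"motif length {L} must be < shortest peak interval {shortest}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome = {
        chrom: rng.integers(0, 4, size=config.chrom_length_bp)
        for chrom in config.chromosome_names()
    }
    insertions: list[tuple[str, int]] = []
    n_plant = int(round(planted_fraction * len(truth.true_peaks)))
    if n_plant:
        idx = rng.choice(len(truth.true_peaks), size=n_plant, replace=False)
        motif_codes = np.array(["ACGT".index(b) for b in motif_consensus])
        for i in sorted(idx):
            chrom, s, e, _name = truth.true_peaks[i]
            offset = int(rng.integers(s, e - L + 2))  # 1-based insertion start
            genome[chrom][offset - 1 : offset - 1 + L] = motif_codes
            insertions.append((chrom, offset))
    seqs = {chrom: "".join(bases[codes]) for chrom, codes in genome.items()}
    return seqs, insertions


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")
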