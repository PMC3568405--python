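"""PWM motif enrichment of peak sequences against randomized backgrounds.

Each 250 bp binding-site sequence is scored against a position weight
matrix as the mean likelihood ratio over all valid windows on both
strands; the peak-set statistic is the mean per-sequence score. Its null
distribution comes from repeatedly drawing equally many fragments from a
large pool of random same-size genomic fragments, giving an add-one
empirical p-value (resolution 1/(n_randomizations + 1)). Masked (N or
lowercase) positions are skipped rather than penalized.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """Probabilistic motif model: per-position base probabilities."""

    name: str
    matrix: np.ndarray  # shape (4, L): rows A,C,G,T; columns positions
    pseudocount: float = 0.01
    background: np.ndarray = None  # length-4 base frequencies

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"PWM {self.name}: need a 4 x L matrix with L >= 4")
        if np.any(np.abs(self.matrix.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.01,
                    background: np.ndarray | None = None) -> "PWM":
        """Build from a position-frequency (count) matrix: pseudocount added
        per cell, then columns normalized."""
        counts = np.asarray(counts, dtype=np.float64) + pseudocount
        return cls(name, counts / counts.sum(axis=0, keepdims=True),
                   pseudocount=pseudocount, background=background)

    def log_odds(self) -> np.ndarray:
        """(L, 4) log likelihood-ratio table, position-major."""
        return np.log(self.matrix.T) - np.log(self.background)[None, :]


def read_jaspar_pfms(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read JASPAR-style PFM text: a '>' header then four count rows
    (optionally labelled ``A [ ... ]``), one motif after another."""
    pwms: list[PWM] = []
    name, rows = None, []
    def flush():
        if name is not None:
            if len(rows) != 4:
                raise ValueError(f"PWM {name}: expected 4 count rows, got {len(rows)}")
            pwms.append(PWM.from_counts(name, np.array(rows), pseudocount))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
            else:
                cleaned = line.replace("[", " ").replace("]", " ")
                parts = cleaned.split()
                if parts and parts[0].upper() in _CODE:
                    parts = parts[1:]
                rows.append([float(x) for x in parts])
    flush()
    return pwms


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A/C/G/T to 0..3; N, lowercase (masked) and anything else to -1."""
    out = np.full(len(sequence), -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def sequence_score(pwm: PWM, sequence: str) -> float:
    """Mean likelihood ratio over all valid windows on both strands.

    A window is valid when all its positions are unmasked A/C/G/T. Raises
    if the sequence is shorter than the motif or has no valid window.
    """
    L = pwm.length
    if len(sequence) < L:
        raise ValueError(f"sequence shorter than motif ({len(sequence)} < {L})")
    codes = encode_sequence(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(windows >= 0, axis=1)
    if not np.any(valid):
        raise ValueError("no unmasked window in sequence")
    w = windows[valid].astype(np.int64)
    llr = pwm.log_odds()  # (L, 4)
    fwd = llr[np.arange(L)[None, :], w].sum(axis=1)
    # reverse strand: complement bases and reverse positions
    llr_rc = llr[::-1, ::-1]
    rev = llr_rc[np.arange(L)[None, :], w].sum(axis=1)
    return float(np.mean(np.exp(np.concatenate([fwd, rev]))))


def peak_set_statistic(pwm: PWM, peak_sequences: list[str]) -> float:
    """Arithmetic mean of per-sequence scores; unscorable sequences are
    excluded with a warning."""
    scores = score_sequences(pwm, peak_sequences)
    if not scores.size:
        raise ValueError("all sequences excluded; nothing to score")
    return float(scores.mean())


def score_sequences(pwm: PWM, sequences: list[str]) -> np.ndarray:
    scores = []
    for i, s in enumerate(sequences):
        try:
            scores.append(sequence_score(pwm, s))
        except ValueError as exc:
            warnings.warn(f"sequence {i} excluded: {exc}", stacklevel=2)
    return np.array(scores)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(Path(path)), "fasta")}


def extract_peak_sequences(genome: dict[str, str], peaks) -> list[str]:
    """Slice 1-based inclusive peak spans out of chromosome sequences."""
    out = []
    for p in peaks:
        seq = genome[p.chromosome]
        out.append(seq[p.start - 1 : p.end])
    return out


def background_fragments(genome: dict[str, str], n: int = 10_000,
                         size_bp: int = 250, chromosomes: list[str] | None = None,
                         seed: int = 0) -> list[str]:
    """n random fragments of fixed size, split evenly across the named
    chromosomes, uniform random start positions."""
    chroms = sorted(genome) if chromosomes is None else list(chromosomes)
    if not chroms:
        raise ValueError("no chromosomes to sample from")
    for c in chroms:
        if len(genome[c]) < size_bp:
            raise ValueError(f"chromosome {c} shorter than fragment size {size_bp}")
    rng = np.random.default_rng(seed)
    per = n // len(chroms)
    counts = [per] * len(chroms)
    for i in range(n - per * len(chroms)):
        counts[i] += 1
    frags: list[str] = []
    for c, m in zip(chroms, counts):
        starts = rng.integers(0, len(genome[c]) - size_bp + 1, size=m)
        frags.extend(genome[c][s : s + size_bp] for s in starts)
    return frags


@dataclass
class EnrichmentResult:
    pwm_name: str
    observed: float
    null_n: int
    null_mean: float
    null_sd: float
    p_value: float
    n_peak_sequences: int


def empirical_pvalue(pwm: PWM, peak_sequences: list[str], background: list[str],
                     n_rand: int = 1000, seed: int = 0) -> EnrichmentResult:
    """Randomization test of the peak-set statistic against the background.

    Each of n_rand rounds draws |peaks| background fragments without
    replacement and recomputes the statistic; the add-one empirical p is
    (1 + #{null >= observed}) / (n_rand + 1), never exactly 0.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if len(background) < len(peak_sequences):
        raise ValueError("background must hold at least as many sequences as the peak set")
    observed_scores = score_sequences(pwm, peak_sequences)
    if not observed_scores.size:
        raise ValueError("all peak sequences excluded")
    observed = float(observed_scores.mean())
    bg_scores = score_sequences(pwm, background)
    if bg_scores.size < observed_scores.size:
        raise ValueError("too few scorable background fragments")
    rng = np.random.default_rng(seed)
    k = len(observed_scores)
    null = np.empty(n_rand)
    for r in range(n_rand):
        idx = rng.choice(bg_scores.size, size=k, replace=False)
        null[r] = bg_scores[idx].mean()
    p = (1.0 + int(np.sum(null >= observed))) / (n_rand + 1.0)
    return EnrichmentResult(
        pwm_name=pwm.name, observed=observed, null_n=n_rand,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)) if n_rand > 1 else 0.0,
        p_value=p, n_peak_sequences=len(observed_scores),
    )
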