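"""Two-state Gaussian-emission HMM segmentation of probe tracks.

An independent, parallel detector to the sliding-window scan: one Gaussian
distribution characterizes non-binding probe intensities and one binding
intensities, with a 2x2 transition matrix capturing the neighbor effect.
Parameters are estimated by Baum-Welch (EM) per replicate, chromosomes
entering as independent observation sequences sharing one parameter set;
bound regions are maximal Viterbi runs of the bound state.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .core import ProbeTrack, Region

SIGMA_FLOOR = 1e-3
UNBOUND, BOUND = 0, 1


@dataclass
class HmmModel:
    """Fitted two-state model; state 0 = unbound, state 1 = bound (mu ordered)."""

    means: tuple[float, float]  # (mu_unbound, mu_bound), log2-ratio units
    sds: tuple[float, float]
    transmat: np.ndarray  # 2x2, rows sum to 1
    startprob: np.ndarray  # length 2
    log_likelihoods: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.transmat = np.asarray(self.transmat, dtype=np.float64)
        self.startprob = np.asarray(self.startprob, dtype=np.float64)
        if self.means[1] < self.means[0]:
            raise ValueError("state means must be ordered: mu_bound >= mu_unbound")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if min(self.sds) < SIGMA_FLOOR - 1e-12:
            raise ValueError(f"state sds must be >= {SIGMA_FLOOR}")

    def to_dict(self) -> dict:
        return {
            "means": list(self.means),
            "sds": list(self.sds),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "log_likelihoods": self.log_likelihoods,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(
            means=tuple(d["means"]), sds=tuple(d["sds"]),
            transmat=np.array(d["transmat"]), startprob=np.array(d["startprob"]),
            log_likelihoods=list(d.get("log_likelihoods", [])),
            n_iter=d.get("n_iter", 0), converged=d.get("converged", False),
        )

    def as_gaussian_hmm(self) -> GaussianHMM:
        m = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        m.startprob_ = self.startprob.copy()
        m.transmat_ = self.transmat.copy()
        m.means_ = np.array([[self.means[0]], [self.means[1]]])
        m.covars_ = np.array([[self.sds[0] ** 2], [self.sds[1] ** 2]])
        return m


def auto_init(values: np.ndarray) -> HmmModel:
    """Symmetry-breaking initialization toward a rare high (bound) state:
    means at the 50th and 97.5th value percentiles, a common MAD-based sigma,
    self-transitions 0.99."""
    mu0 = float(np.percentile(values, 50.0))
    mu1 = float(np.percentile(values, 97.5))
    if mu1 - mu0 < 1e-6:
        mu1 = mu0 + 1.0  # degenerate spread; separate arbitrarily
    sigma = max(float(1.4826 * np.median(np.abs(values - np.median(values)))), SIGMA_FLOOR)
    return HmmModel(
        means=(mu0, mu1),
        sds=(sigma, sigma),
        transmat=np.array([[0.99, 0.01], [0.01, 0.99]]),
        startprob=np.array([0.9, 0.1]),
    )


def fit_hmm(tracks: dict[str, ProbeTrack], init: HmmModel | str = "auto",
            tol: float = 1e-4, max_iter: int = 100) -> HmmModel:
    """Baum-Welch fit of the two-state model to one replicate.

    Chromosomes are independent observation sequences sharing one parameter
    set. EM runs until the relative log-likelihood change drops below
    ``tol`` or ``max_iter`` sweeps; states are relabelled afterwards so that
    mu_bound > mu_unbound and sigma is clamped at a small floor.
    """
    chroms = sorted(tracks)
    values = np.concatenate([tracks[c].values for c in chroms])
    lengths = [len(tracks[c]) for c in chroms]
    if values.size < 100:
        raise ValueError(f"need >= 100 probes to fit, got {values.size}")

    if float(np.std(values)) < SIGMA_FLOOR:
        warnings.warn("constant input: returning degenerate model", stacklevel=2)
        v = float(values[0])
        return HmmModel(
            means=(v, v), sds=(SIGMA_FLOOR, SIGMA_FLOOR),
            transmat=np.array([[0.99, 0.01], [0.01, 0.99]]),
            startprob=np.array([0.9, 0.1]),
            converged=True,
        )

    model0 = auto_init(values) if init == "auto" else init
    m = GaussianHMM(
        n_components=2, covariance_type="diag", init_params="", params="stmc",
        n_iter=max_iter, tol=tol * abs(values.size), min_covar=SIGMA_FLOOR**2,
    )
    m.startprob_ = model0.startprob.copy()
    m.transmat_ = model0.transmat.copy()
    m.means_ = np.array([[model0.means[0]], [model0.means[1]]])
    m.covars_ = np.array([[model0.sds[0] ** 2], [model0.sds[1] ** 2]])
    X = values.reshape(-1, 1)
    m.fit(X, lengths=lengths)
    history = [float(v) for v in m.monitor_.history]
    if not np.all(np.isfinite(history)):
        raise RuntimeError("non-finite log-likelihood during EM")

    means = m.means_.ravel()
    sds = np.sqrt(m.covars_.ravel())
    order = np.argsort(means)  # unbound first
    if np.any(sds[order] < SIGMA_FLOOR):
        warnings.warn("emission variance collapsed; clamping sigma", stacklevel=2)
        sds = np.maximum(sds, SIGMA_FLOOR)
    transmat = m.transmat_[np.ix_(order, order)]
    transmat = transmat / transmat.sum(axis=1, keepdims=True)
    startprob = m.startprob_[order]
    startprob = startprob / startprob.sum()
    return HmmModel(
        means=(float(means[order[0]]), float(means[order[1]])),
        sds=(float(sds[order[0]]), float(sds[order[1]])),
        transmat=transmat,
        startprob=startprob,
        log_likelihoods=history,
        n_iter=int(m.monitor_.iter),
        converged=bool(m.monitor_.converged),
    )


def viterbi_path(values: np.ndarray, model: HmmModel) -> np.ndarray:
    """Most probable state path (log-space Viterbi) for one value sequence."""
    m = model.as_gaussian_hmm()
    return m.predict(np.asarray(values, dtype=np.float64).reshape(-1, 1))


def bound_posterior(values: np.ndarray, model: HmmModel) -> np.ndarray:
    """Forward-backward posterior probability of the bound state per probe."""
    m = model.as_gaussian_hmm()
    return m.predict_proba(np.asarray(values, dtype=np.float64).reshape(-1, 1))[:, BOUND]


def decode_bound_regions(track: ProbeTrack, model: HmmModel, min_run: int = 3,
                         replicate: int | None = None) -> list[Region]:
    """Maximal Viterbi runs of the bound state with >= min_run probes.

    Each region spans the first to last probe position of the run; its
    score is the mean forward-backward posterior of the bound state over
    the run's probes.
    """
    if len(track) == 0:
        return []
    path = viterbi_path(track.values, model)
    post = bound_posterior(track.values, model)
    regions: list[Region] = []
    i = 0
    n = len(path)
    while i < n:
        if path[i] == BOUND:
            j = i
            while j + 1 < n and path[j + 1] == BOUND:
                j += 1
            if j - i + 1 >= min_run:
                regions.append(
                    Region(
                        chromosome=track.chromosome,
                        start=int(track.positions[i]),
                        end=int(track.positions[j]),
                        score=float(post[i : j + 1].mean()),
                        source="hmm",
                        replicate=replicate,
                    )
                )
            i = j + 1
        else:
            i += 1
    return regions


def segment_replicate(tracks: dict[str, ProbeTrack], init: HmmModel | str = "auto",
                      tol: float = 1e-4, max_iter: int = 100, min_run: int = 3,
                      replicate: int | None = None) -> tuple[HmmModel, list[Region]]:
    """Fit one model to a replicate and decode bound regions per chromosome."""
    model = fit_hmm(tracks, init=init, tol=tol, max_iter=max_iter)
    regions: list[Region] = []
    for chrom in sorted(tracks):
        regions.extend(decode_bound_regions(tracks[chrom], model, min_run, replicate))
    return model, regions
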