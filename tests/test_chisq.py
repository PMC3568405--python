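import math

import numpy as np
import pytest
from scipy import stats

from chiptile import chisq
from chiptile.core import ProbeTrack
from chiptile.simulate import SimConfig, simulate_annotation, simulate_tracks


def chi2_sf_oracle(x):
    """chi-square(1) upper tail via the error function, independent of scipy."""
    return math.erfc(math.sqrt(x / 2.0))


# ---------------------------------------------------------------------------
# threshold


def test_threshold_linear_interpolated_quantile():
    track = {"chr1": ProbeTrack("chr1", np.arange(1, 101), np.arange(1.0, 101.0))}
    assert chisq.compute_threshold(track, 0.95) == pytest.approx(95.05)


def test_threshold_constant_track_yields_no_probes_above():
    track = {"chr1": ProbeTrack("chr1", np.arange(1, 101), np.full(100, 1.5))}
    thr = chisq.compute_threshold(track, 0.95)
    assert thr == 1.5
    assert not np.any(track["chr1"].values > thr)


def test_threshold_median_at_half():
    vals = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
    track = {"chr1": ProbeTrack("chr1", np.arange(1, 6), vals)}
    assert chisq.compute_threshold(track, 0.5) == np.median(vals)


def test_threshold_empty_errors():
    with pytest.raises(ValueError):
        chisq.compute_threshold({}, 0.95)


# ---------------------------------------------------------------------------
# the one-tailed chi-square test


def test_worked_statistic_and_pvalue():
    """n=10, k=8, p0=0.05: X = (8 - 0.5)^2 / (10*0.05*0.95) = 118.42."""
    k, n, p0 = 8, 10, 0.05
    x = (k - n * p0) ** 2 / (n * p0 * (1 - p0))
    assert x == pytest.approx(118.42, abs=1e-2)
    p = chisq.chisq_upper_p(np.array([k]), np.array([n]), p0)[0]
    assert p == pytest.approx(chi2_sf_oracle(118.42), rel=1e-3)


def test_k_at_expectation_gives_p_one():
    assert chisq.chisq_upper_p(np.array([0.5]), np.array([10]), 0.05)[0] == 1.0
    assert chisq.chisq_upper_p(np.array([0]), np.array([10]), 0.05)[0] == 1.0


def test_all_values_below_threshold_give_all_p_one():
    track = ProbeTrack("chr1", np.arange(1, 3201, 32), np.zeros(100))
    p = chisq.window_chisq(track, 600, threshold=1.0, p0=0.05)
    assert np.all(p == 1.0)


def test_raising_a_value_never_increases_window_p():
    rng = np.random.default_rng(4)
    values = rng.normal(0, 0.5, 200)
    track = ProbeTrack("chr1", np.arange(1, 1 + 32 * 200, 32), values)
    p_before = chisq.window_chisq(track, 600, threshold=1.0, p0=0.05)
    bumped = values.copy()
    bumped[100] = 5.0  # push one value above the threshold
    track2 = ProbeTrack("chr1", track.positions, bumped)
    p_after = chisq.window_chisq(track2, 600, threshold=1.0, p0=0.05)
    assert np.all(p_after <= p_before + 1e-15)


def test_rank_agreement_with_exact_binomial_at_operating_p0():
    """One-tailed chi2(1) p ranks like the exact binomial upper tail over
    random small-n configurations at the detector's operating p0."""
    rng = np.random.default_rng(2024)
    p0 = 0.05
    n = rng.integers(1, 13, 1000)
    k = np.array([rng.integers(0, m + 1) for m in n])
    p_chi = chisq.chisq_upper_p(k, n, p0)
    p_bin = stats.binom.sf(k - 1, n, p0)
    rho = stats.spearmanr(p_chi, p_bin).statistic
    assert rho > 0.99


# ---------------------------------------------------------------------------
# region fusing


def _pvals_from_significance(sig, cutoff=1e-4):
    p = np.ones(len(sig))
    p[np.asarray(sig, bool)] = cutoff / 10
    return p


def test_no_significant_probes_no_regions():
    track = ProbeTrack("chr1", np.arange(1, 101), np.zeros(100))
    pv = {600: np.ones(100), 800: np.ones(100), 1000: np.ones(100)}
    assert chisq.significant_regions(track, pv, chisq.ScanParams()) == []


def test_gap_rule_splits_runs():
    # fully tiled track: significant at 100/132/164 and again at 1000
    positions = np.arange(100, 1100, 32)
    sig = np.isin(positions, [100, 132, 164, 1060])
    track = ProbeTrack("chr1", positions, np.zeros(len(positions)))
    pv = {w: _pvals_from_significance(sig) for w in (600, 800, 1000)}
    regions = chisq.significant_regions(track, pv, chisq.ScanParams(max_gap_probes=2))
    assert [(r.start, r.end) for r in regions] == [(100, 164), (1060, 1060)]


def test_gap_rule_fuses_across_small_gaps():
    positions = np.arange(100, 500, 32)
    sig = np.isin(positions, [100, 196])  # 2 intervening non-significant probes
    track = ProbeTrack("chr1", positions, np.zeros(len(positions)))
    pv = {w: _pvals_from_significance(sig) for w in (600, 800, 1000)}
    regions = chisq.significant_regions(track, pv, chisq.ScanParams(max_gap_probes=2))
    assert [(r.start, r.end) for r in regions] == [(100, 196)]


def test_combine_rules():
    sig_a = np.array([1e-6, 1.0, 1e-6])
    sig_b = np.array([1e-6, 1e-6, 1.0])
    sig_c = np.array([1e-6, 1e-6, 1.0])
    pv = {600: sig_a, 800: sig_b, 1000: sig_c}
    inter = chisq.combine_significance(pv, chisq.ScanParams(combine_rule="intersection"))
    union = chisq.combine_significance(pv, chisq.ScanParams(combine_rule="union"))
    any2 = chisq.combine_significance(pv, chisq.ScanParams(combine_rule="any-k", combine_k=2))
    assert list(inter) == [True, False, False]
    assert list(union) == [True, True, True]
    assert list(any2) == [True, True, False]


def test_single_planted_peak_yields_one_overlapping_region():
    """One 800 bp peak at amplitude/sigma = 4 in an otherwise empty genome is
    found as exactly one region with >= 50% reciprocal overlap."""
    cfg = SimConfig(n_chromosomes=1, n_orfs=1, n_tdnas=0, n_snornas=0, n_arss=0,
                    bound_fraction_per_class={"ORF": 1.0}, replicate_noise_peaks=0,
                    n_replicates=1, seed=21)
    feats = simulate_annotation(cfg)
    reps, truth = simulate_tracks(feats, cfg)
    assert len(truth.true_peaks) == 1
    regions = chisq.scan_replicate(reps[0], chisq.ScanParams())
    assert len(regions) == 1
    _, s, e, _ = truth.true_peaks[0]
    r = regions[0]
    overlap = max(0, min(e, r.end) - max(s, r.start) + 1)
    assert overlap >= 0.5 * (e - s + 1)
    assert overlap >= 0.5 * r.width


def test_false_positive_rate_bounded_under_pure_background():
    cfg = SimConfig(bound_fraction_per_class={}, replicate_noise_peaks=0,
                    n_replicates=1, seed=13)
    feats = simulate_annotation(cfg)
    reps, _ = simulate_tracks(feats, cfg)
    tracks = reps[0]
    thr = chisq.compute_threshold(tracks, 0.95)
    p0 = 0.05
    cutoff = 1e-4
    for w in (600, 800, 1000):
        frac_sig = np.mean([
            (chisq.window_chisq(t, w, thr, p0) < cutoff).mean()
            for t in tracks.values()
        ])
        assert frac_sig <= 5 * cutoff * (w / cfg.probe_spacing_bp)
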