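import numpy as np
import pytest

from chiptile import annotate, metagene
from chiptile.core import Feature, FeatureTable, ProbeTrack


def uniform_track(chrom, length, spacing, values):
    pos = np.arange(1, length + 1, spacing)
    return ProbeTrack(chrom, pos, values(pos) if callable(values) else
                      np.full(len(pos), values))


def test_constant_signal_gives_flat_profile():
    signal = {"chr1": uniform_track("chr1", 50_000, 32, 1.7)}
    features = FeatureTable([
        Feature("A", "chr1", 5000, 7000, "+", "ORF"),
        Feature("B", "chr1", 20_000, 21_500, "-", "ORF"),
    ])
    prof = metagene.average_profile(signal, features)
    means = prof.bin_means
    filled = means[~np.isnan(means)]
    assert len(filled) > 0
    assert np.allclose(filled, 1.7, atol=1e-12)


def test_linear_gradient_gives_increasing_body_bins():
    # signal increases linearly along the body of a plus-strand feature
    signal = {"chr1": uniform_track("chr1", 50_000, 16, lambda p: p / 1000.0)}
    features = FeatureTable([Feature("A", "chr1", 10_000, 20_000, "+", "ORF")])
    prof = metagene.average_profile(signal, features)
    body = prof.bin_means[prof.n_flank_bins: prof.n_flank_bins + prof.n_body_bins]
    assert not np.any(np.isnan(body))
    assert np.all(np.diff(body) > 0)
    # independent recomputation of one bin mean
    t = signal["chr1"]
    width = 10_001 / 50
    lo, hi = 10_000 + 10 * width, 10_000 + 11 * width
    mask = (t.positions >= lo) & (t.positions < hi)
    assert body[10] == pytest.approx(t.values[mask].mean())


def test_strand_mirror_symmetry():
    """A minus-strand feature with the mirror-image signal profiles
    identically to its plus-strand counterpart."""
    n = 2000
    pos = np.arange(1, n * 16 + 1, 16)
    ramp = np.linspace(0, 1, len(pos))
    sig_plus = {"chr1": ProbeTrack("chr1", pos, ramp)}
    L = pos[-1] + 15
    # exact mirror image: probe at p maps to L - p + 1 with the same value
    sig_minus = {"chr1": ProbeTrack("chr1", (L + 1 - pos)[::-1].copy(),
                                    ramp[::-1].copy())}
    span = (8001, 24_000)
    f_plus = FeatureTable([Feature("A", "chr1", span[0], span[1], "+", "ORF")])
    # mirror position of [s, e] in [1, L]: (L - e + 1, L - s + 1)
    f_minus = FeatureTable([Feature("A", "chr1", L - span[1] + 1, L - span[0] + 1,
                                    "-", "ORF")])
    p1 = metagene.average_profile(sig_plus, f_plus)
    p2 = metagene.average_profile(sig_minus, f_minus)
    m1, m2 = p1.bin_means, p2.bin_means
    ok = ~(np.isnan(m1) | np.isnan(m2))
    assert np.allclose(m1[ok], m2[ok], atol=1e-9)
    assert np.array_equal(p1.bin_counts, p2.bin_counts)


def test_probe_contribution_conservation():
    rng = np.random.default_rng(2)
    signal = {"chr1": uniform_track("chr1", 100_000, 32,
                                    lambda p: rng.normal(size=len(p)))}
    features = FeatureTable([
        Feature("A", "chr1", 5000, 8000, "+", "ORF"),
        Feature("B", "chr1", 8300, 12_000, "-", "ORF"),  # flanks overlap A's
    ])
    prof = metagene.average_profile(signal, features)
    t = signal["chr1"]
    fw = np.mean([f.length for f in features]) / 50
    flank_span = prof.n_flank_bins * fw
    expected = 0
    for f in features:
        lo, hi = f.start - flank_span, f.end + 1 + flank_span
        expected += int(np.sum((t.positions >= lo) & (t.positions < hi)))
    assert int(prof.bin_counts.sum()) == expected


def test_short_feature_skipped_with_warning():
    signal = {"chr1": uniform_track("chr1", 10_000, 32, 1.0)}
    features = FeatureTable([
        Feature("tiny", "chr1", 100, 130, "+", "ORF"),
        Feature("ok", "chr1", 3000, 6000, "+", "ORF"),
    ])
    with pytest.warns(UserWarning, match="tiny"):
        prof = metagene.average_profile(signal, features)
    assert prof.n_features == 1


def test_empty_bins_reported_as_nan_not_zero():
    # probes every 512 bp leave many 50-bp-scale bins empty
    signal = {"chr1": uniform_track("chr1", 50_000, 512, 2.0)}
    features = FeatureTable([Feature("A", "chr1", 10_000, 12_500, "+", "ORF")])
    prof = metagene.average_profile(signal, features)
    assert np.any(np.isnan(prof.bin_means))
    assert np.nanmax(np.abs(prof.bin_means - 2.0)) < 1e-12


# ---------------------------------------------------------------------------
# rate classes


def test_rate_partition():
    features = FeatureTable([
        Feature("a", "chr1", 100, 1000, "+", "ORF"),
        Feature("b", "chr1", 2000, 3000, "+", "ORF"),
        Feature("c", "chr1", 4000, 5000, "+", "ORF"),
    ])
    groups = metagene.classify_by_rate(features, {"a": 20.0, "b": 5.0, "c": 0.5})
    assert [f.name for f in groups["high"]] == ["a"]
    assert [f.name for f in groups["medium"]] == ["b"]
    assert [f.name for f in groups["low"]] == ["c"]
    assert len(groups["unclassified"]) == 0


def test_rate_edge_ownership():
    spec = metagene.RateClassSpec()
    assert spec.classify(15.0) == "high"
    assert spec.classify(1.0) == "low"
    assert spec.classify(14.999) == "medium"
    assert spec.classify(1.001) == "medium"


def test_rate_missing_gene_goes_to_unclassified():
    features = FeatureTable([Feature("a", "chr1", 100, 1000, "+", "ORF")])
    groups = metagene.classify_by_rate(features, {})
    assert [f.name for f in groups["unclassified"]] == ["a"]


def test_negative_rate_rejected():
    with pytest.raises(ValueError, match="negative"):
        metagene.RateClassSpec().classify(-1.0)


def test_rate_classes_partition_simulated_genes(sim_dataset):
    features, _, truth = sim_dataset
    orfs = features.by_class("ORF")
    groups = metagene.classify_by_rate(orfs, truth.rates)
    sizes = {k: len(v) for k, v in groups.items()}
    assert sum(sizes.values()) == len(orfs)
    assert sizes["unclassified"] == 0
    assert all(sizes[k] > 0 for k in ("high", "medium", "low"))


# ---------------------------------------------------------------------------
# bound-subset profiles


def test_bound_subset_identical_when_all_bound():
    signal = {"chr1": uniform_track("chr1", 50_000, 32, 1.0)}
    features = FeatureTable([
        Feature("A", "chr1", 5000, 7000, "+", "ORF"),
        Feature("B", "chr1", 20_000, 22_000, "-", "ORF"),
    ])
    assigns = [annotate.PeakAssignment("p1", "chr1", 6000, "A", "ORF", 0),
               annotate.PeakAssignment("p2", "chr1", 21_000, "B", "ORF", 0)]
    full = metagene.average_profile(signal, features)
    bound = metagene.bound_subset_profile(signal, features, assigns)
    assert np.array_equal(full.bin_counts, bound.bin_counts)
    ok = full.bin_counts > 0
    assert np.allclose(full.bin_means[ok], bound.bin_means[ok])


def test_bound_subset_empty_errors():
    signal = {"chr1": uniform_track("chr1", 50_000, 32, 1.0)}
    features = FeatureTable([Feature("A", "chr1", 5000, 7000, "+", "ORF")])
    with pytest.raises(ValueError, match="orfs"):
        metagene.bound_subset_profile(signal, features, [], label="orfs")


def test_bound_orfs_show_five_prime_enrichment(sim_dataset, normalized_replicates,
                                               called_peaks):
    """Planted peaks sit at/around ORF 5' ends, so the 5' half of the bound
    ORF profile must exceed the 3' half."""
    features, _, _ = sim_dataset
    peaks, _, _ = called_peaks
    signal = metagene.average_tracks(normalized_replicates)
    assigns = annotate.assign_peaks(peaks, features)
    orfs = features.by_class("ORF")
    prof = metagene.bound_subset_profile(signal, orfs, assigns)
    body = prof.bin_means[prof.n_flank_bins: prof.n_flank_bins + prof.n_body_bins]
    five_half = np.nanmean(body[:25])
    three_half = np.nanmean(body[25:])
    assert five_half > three_half


def test_average_tracks_requires_matching_positions():
    a = {"chr1": ProbeTrack("chr1", np.arange(1, 100, 32), np.zeros(4))}
    b = {"chr1": ProbeTrack("chr1", np.arange(2, 101, 32), np.zeros(4))}
    with pytest.raises(ValueError, match="positions"):
        metagene.average_tracks([a, b])
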