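# Methods

## Signal model and normalization

The observable is the per-probe log₂(IP/input) hybridization ratio of a
genome tiling array. Each replicate array is normalized independently by
subtracting the iterated Tukey biweight location of its pooled values
(tuning constant c = 5, tolerance 1e-6, ≤ 100 iterations). Centering is
done on the log scale; whether the original array software scaled or
centered is not recoverable from a ratio track, and centering is the
variant that leaves downstream statistics shift-free. If the MAD is zero
(degenerate input) the estimator falls back to the median with a
warning. On data where no point is down-weighted the biweight equals the
arithmetic mean, which the tests assert.

## Sliding-window χ² detector

The scan assumes only (i) enrichment is one-tailed positive and (ii)
true signal spans several neighboring probes. Probes are dichotomized at
the empirical quantile `threshold_percentile` (default 0.95, linear
interpolation) of the replicate's pooled values; by construction the
genome-wide above-threshold proportion is `p0 = 1 − threshold_percentile`
exactly, so p0 is not re-estimated. For each window size (600, 800,
1000 bp, centered at every probe) the above-threshold count k of the n
in-window probes gives the 1-df goodness-of-fit statistic
X = (k − n·p0)² / (n·p0·(1 − p0)) without Yates correction; evidence is
zeroed (p = 1) when k ≤ n·p0. A probe is significant when p <
`p_cutoff` (default 1e-4) under the `combine_rule` across window sizes
(default: all three — the most conservative reading of running the
windows "separately"; union and any-k are selectable). Runs of
significant probes with at most `max_gap_probes` (default 2)
non-significant probes between neighbors fuse into regions scored by
their minimum p.

Numerical notes: the window membership test is closed ([c − w/2,
c + w/2] by probe midpoint), windows are never empty because each is
centered at a probe, and the χ²(1) approximation is rank-faithful to the
exact binomial tail at the operating p0 = 0.05 (Spearman ρ ≈ 0.99 over
random n ≤ 12 configurations; asserted in tests). At substantially
larger or heterogeneous p0 the continuity error of the 1-df
approximation breaks strict rank agreement — a known limit of the
dichotomized test, not of this implementation.

## Two-state Gaussian HMM detector

A parallel, assumption-complementary detector: emissions are
N(μ_unbound, σ_unbound) and N(μ_bound, σ_bound) with a full 2×2
transition matrix, one parameter set per replicate, chromosomes entering
Baum–Welch as independent sequences. Initialization breaks label
symmetry toward a rare bound state: means at the 50th and 97.5th value
percentiles, a common MAD-based σ, self-transitions 0.99. After
fitting, states are relabelled so μ_bound > μ_unbound (making the
procedure invariant to label-swapped initializations), σ is clamped at a
1e-3 floor, and constant input short-circuits to a degenerate model with
a warning. Regions are maximal Viterbi runs of the bound state of at
least `min_run` probes (default 3, suppressing single-probe calls);
the reported score is the mean forward–backward posterior of the bound
state over the run. Viterbi rather than posterior thresholding defines
regions because contiguous-run semantics match the region contract; the
posterior is kept as the confidence score. Fitting and decoding are
delegated to hmmlearn's GaussianHMM; tests verify the EM monotonicity,
parameter recovery from a known generating chain, and exact agreement of
Viterbi with brute-force path enumeration.

## Consensus: intersection, merging, trimming

Within a replicate, only base-pair intersections of overlapping χ²-scan
and HMM regions (≥ 1 bp) survive; the intersection carries the more
extreme member score. Across replicates, region midpoints on each
chromosome are clustered by single linkage with threshold
< 125 bp (strict, matching "less than 125 bp apart"); single linkage is
the simplest rule consistent with pairwise wording, so a chain
1000/1120/1240 merges even though its ends are 240 bp apart. Clusters
containing ≥ 2 distinct replicates become binding sites; if a replicate
contributes two members to one cluster only the member nearest the
cluster mean is kept (logged). The merged midpoint is the floor of the
mean member midpoint, and every site is trimmed to exactly 250 bp as
[midpoint − 124, midpoint + 125] — 250 positions in 1-based inclusive
coordinates, midpoint-preserving under floor re-derivation; sites too
close to a chromosome start are shifted right with a warning.

## Annotation and occupancy statistics

A site is assigned to the feature whose span is nearest its midpoint,
provided that distance is ≤ 125 bp (0 when the midpoint falls inside the
span); otherwise it is intergenic. Peak-edge overlap is deliberately not
used — the proximity contract is midpoint-based. Ties are broken by
class priority tRNA_gene > snoRNA_gene > snRNA_gene > ncRNA_gene > ARS >
ORF, then name: short ncRNA genes sit close to ORFs and would otherwise
be systematically shadowed. Each peak gets exactly one assignment.
Composition is the fraction of all peaks per class (including
intergenic, summing to 1); fraction-bound is the percent of each class's
features carrying ≥ 1 peak (a feature counts once regardless of peak
count); allele occupancy reports (bound, total) over a name-pattern
family, e.g. the genomic copies of one tRNA species.

## Metagene profiles

Replicate tracks are first averaged probe-wise into a single enrichment
surface (the profile describes one occupancy landscape, not per-replicate
variation). Each feature body is split into 50 equal-width bins; flank
bins use the feature set's mean body-bin width and extend to cover
250 bp on each side (n_flank = max(1, round(250/width))), so flank and
body bins are comparable. Probe membership is by midpoint in half-open
[lo, hi) bins — every probe lands in exactly one bin per feature, and a
probe inside two features' windows contributes once to each.
Minus-strand features are reversed before pooling so all profiles read
5′→3′. Bin means pool contributions over all features ("summed and
averaged"); empty bins are reported as missing (NaN), never as 0.
Features shorter than 50 bp are skipped with a warning. Transcription
rate classes partition (0, ∞) as high (rate ≥ 15 mRNAs/hr), low
(rate ≤ 1) and medium (strictly between); the boundary values belong to
the closed outer classes because those are the printed inequalities.
Genes without a rate go to an explicit "unclassified" set. The
baseline profile of a class uses all its genes, bound or not.

## Motif enrichment

Each 250 bp site sequence is scored against a PWM (JASPAR-style counts,
pseudocount 0.01 per cell, columns renormalized) as the mean likelihood
ratio ∏ᵢ pwm[bᵢ,i]/bg[bᵢ] over all valid windows on both strands;
windows touching N or lowercase-masked bases are skipped rather than
penalized. The peak-set statistic is the mean per-sequence score — a
deliberate, documented simplification of a full motif-enrichment raw
score that preserves the testing contract: enrichment is judged against
10,000 random same-size genomic fragments (evenly drawn from the
designated chromosomes), by re-drawing |peaks| fragments n_rand = 1000
times and reporting the add-one empirical p = (1 + #{null ≥ observed}) /
(n_rand + 1), which is never 0 and has resolution 1/(n_rand + 1). Type-I
calibration at the 0.05 threshold is verified by simulation in the
acceptance suite (500 repetitions at n_rand = 200, a scaled-down
randomization count that keeps the check fast at the same resolution
logic).

## Synthetic data generator

The generator emulates the study design at miniature scale: 2
chromosomes × 250 kb, probes of 50 bp tiled every 32 bp (~15.6k probes
— the real array's exact spacing is unpublished, so the 32 bp default is
a stand-in exposed in config), 140 ORFs (500–2000 bp), 40 tDNAs (80 bp),
26 snoRNA genes (150 bp) and 20 ARSs (200 bp) placed without overlap at
≥ 200 bp gaps on both strands. Background ratios are i.i.d. N(0, 0.5).
Enrichment is a flat plateau of +2.0 (amplitude/σ = 4) over a planted
800 bp interval — flat rather than bell-shaped so the truth interval is
well-defined for recovery scoring, and 800 bp because ~300 bp chromatin
fragments smear a point site to window scale on both sides. For
features longer than the peak width the interval anchors at the 5′ end
(¼ upstream, ¾ into the body, giving the expected 5′-biased profiles);
shorter features (tDNAs, snoRNA genes) are covered whole, centered on
the gene. Bound fractions default to the occupancy the analysis is
designed to recover — 10% of ORFs, 40% of tRNA genes, 35% of snoRNA
genes, 25% of ARSs — planting 44 true sites, a density close to real
genome-wide location data (≈ 1 site / 11 kb). True peaks are identical
in all 3 replicates; each replicate additionally gets 30 noise peaks of
the same amplitude placed ≥ 300 bp clear of every other planted
interval, so noise is single-replicate by construction and the ≥ 2-
replicate merge provably removes it. Transcription rates are drawn
log-normal (μ = 1.0, σ = 1.5 on the log scale), which populates all
three rate classes with a realistic skew. The sequence simulator writes
a uniform-random A/C/G/T genome and can insert a motif consensus at a
random offset inside a chosen fraction of true peaks, logging insertion
positions.

What the generator does **not** model: probe sequence bias, dye and
spatial array artifacts, fragment-length smoothing of peak edges,
repeat structure, or correlated background. Passing tests therefore
demonstrate the correctness of the statistics and the
consensus logic under the stated signal model, not robustness to
array-specific artifacts.

## Problem sizes and degenerate inputs

Tests and the acceptance script run the full pipeline at the 2 × 250 kb
default scale (seconds per run) and the motif calibration at 500
repetitions × 200 randomizations over a 300-fragment background; these
sizes are the package's chosen study conditions. Degenerate inputs are
handled explicitly: empty feature tables, constant tracks (quantile
threshold with zero probes above, HMM variance floor), MAD = 0
normalization, features shorter than the bin count, fully masked
sequences, and peaks too close to a chromosome start.

## Known limitations

- At site densities far above ~1 per 5 kb the 0.95-quantile threshold
  migrates into the enriched-value distribution and the χ² scan loses
  power (the above-threshold probe budget is capped at 5% of probes by
  construction). The acceptance suite documents this with a deliberately
  over-crowded 100-site stress configuration on which consensus recovery
  drops well below the near-complete recovery seen at realistic density.
- The χ²-significance cutoffs of the original array analysis are
  unpublished; the defaults here (0.95, 1e-4) are conventional for this
  detector family, and exact site counts from any particular real
  dataset are not reproduced.
- No FDR layer on the window scan, no > 2-state HMM, no IDR-style
  replicate weighting, and no confidence bands on metagene profiles.
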