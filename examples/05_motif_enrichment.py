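"""PWM motif enrichment of binding-site sequences vs randomized backgrounds.

A motif consensus is planted in 60% of the true-peak intervals of a random
genome; the planted PWM should reach a small empirical p-value while a
scrambled control stays unremarkable. The null is built by repeatedly
drawing same-size random genomic fragments.
"""
from chiptile import motif
from chiptile.core import Peak
from chiptile.demo import DEMO_MOTIF, consensus_counts
from chiptile.motif import PWM
from chiptile.simulate import SimConfig, simulate_annotation, simulate_sequences, \
    simulate_tracks

cfg = SimConfig(seed=0)
features = simulate_annotation(cfg)
_, truth = simulate_tracks(features, cfg)
genome, insertions = simulate_sequences(cfg, truth, DEMO_MOTIF,
                                        planted_fraction=0.6, seed=2)
print(f"planted '{DEMO_MOTIF}' in {len(insertions)} of "
      f"{len(truth.true_peaks)} true peaks")

# 250 bp site sequences around the true-peak midpoints
sites = []
for chrom, s, e, _ in truth.true_peaks:
    mid = (s + e) // 2
    sites.append(Peak(chrom, mid - 124, mid + 125, midpoint=mid, support=2))
seqs = motif.extract_peak_sequences(genome, sites)
background = motif.background_fragments(genome, n=2000, size_bp=250, seed=3)

planted_pwm = PWM.from_counts("planted", consensus_counts(DEMO_MOTIF))
scrambled = DEMO_MOTIF[::2] + DEMO_MOTIF[1::2]
control_pwm = PWM.from_counts("scrambled", consensus_counts(scrambled))

for pwm in (planted_pwm, control_pwm):
    res = motif.empirical_pvalue(pwm, seqs, background, n_rand=200, seed=4)
    print(f"{pwm.name:10s} observed = {res.observed:8.2f}  "
          f"null mean = {res.null_mean:6.2f}  p = {res.p_value:.4g}")
# The planted motif hits the resolution floor 1/(n_rand+1) = 0.005 while the
# scrambled control p stays well above the 0.05 threshold.
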