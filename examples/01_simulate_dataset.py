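"""Generate a miniature synthetic ChIP-chip dataset with planted ground truth.

Writes a feature GFF, three replicate probe tracks, a rates table, a genome
FASTA with a planted motif, a PWM file and a ready-to-run pipeline config.
"""
from chiptile.demo import generate_inputs
from chiptile.simulate import SimConfig, SimTruth

paths = generate_inputs("example_out/dataset", SimConfig(seed=0))
truth = SimTruth.from_json(paths["truth_json"])

print(f"wrote {len(paths)} artifacts under example_out/dataset/")
print(f"planted true peaks     : {len(truth.true_peaks)}")
print(f"noise peaks/replicate  : {len(truth.noise_peaks[0])}")
print(f"genes with rates       : {len(truth.rates)}")
# The true peaks are identical in every replicate; each noise peak exists in
# exactly one replicate, which is what the >=2-replicate consensus rule removes.
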