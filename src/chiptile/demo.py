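"""One-command synthetic demo: write a full miniature input set to disk.

Generates the annotation, three replicate probe tracks with planted peaks,
per-gene transcription rates, a genome FASTA carrying a planted motif in a
fraction of the true binding sites, a small PWM file (the planted motif
plus a scrambled control), the ground-truth JSON and a ready-to-run
pipeline config. Everything downstream can then be exercised end-to-end
with no external data.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import io
from .simulate import SimConfig, simulate_annotation, simulate_sequences, \
    simulate_tracks, write_fasta

DEMO_MOTIF = "TGACTCATCG"
DEMO_PLANTED_FRACTION = 0.6


def consensus_counts(consensus: str, strength: int = 20) -> np.ndarray:
    counts = np.ones((4, len(consensus)))
    for i, b in enumerate(consensus):
        counts["ACGT".index(b), i] = strength
    return counts


def write_pwm_file(path, motifs: dict[str, str], strength: int = 20) -> None:
    """Write consensus strings as JASPAR-style count matrices."""
    with open(path, "w") as fh:
        for name, consensus in motifs.items():
            counts = consensus_counts(consensus, strength)
            fh.write(f">{name}\n")
            for base, row in zip("ACGT", counts):
                fh.write(f"{base} [ " + " ".join(f"{int(x)}" for x in row) + " ]\n")


def generate_inputs(outdir, config: SimConfig | None = None,
                    motif_consensus: str = DEMO_MOTIF,
                    planted_fraction: float = DEMO_PLANTED_FRACTION) -> dict:
    """Simulate a dataset and write every pipeline input under ``outdir``.

    Returns a dict of paths, including a ``config`` YAML that points at them.
    """
    config = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    features = simulate_annotation(config)
    replicates, truth = simulate_tracks(features, config)
    genome, insertions = simulate_sequences(
        config, truth, motif_consensus, planted_fraction, seed=config.seed + 2)

    paths = {}
    io.write_feature_gff(features, outdir / "features.gff")
    paths["feature_gff"] = str(outdir / "features.gff")
    track_paths = []
    for i, tracks in enumerate(replicates, 1):
        p = outdir / f"replicate_{i}.track.tsv"
        io.write_probe_track(tracks, p)
        track_paths.append(str(p))
    paths["probe_tracks"] = track_paths
    io.write_rates_tsv(truth.rates, outdir / "rates.tsv")
    paths["rates_tsv"] = str(outdir / "rates.tsv")
    truth.to_json(outdir / "truth.json")
    paths["truth_json"] = str(outdir / "truth.json")
    write_fasta(genome, outdir / "genome.fa")
    paths["fasta"] = str(outdir / "genome.fa")
    scrambled = motif_consensus[::2] + motif_consensus[1::2]
    write_pwm_file(outdir / "pwms.txt",
                   {"planted": motif_consensus, "scrambled_control": scrambled})
    paths["pwm_file"] = str(outdir / "pwms.txt")
    with open(outdir / "insertions.tsv", "w") as fh:
        fh.write("chromosome\tposition\n")
        for chrom, pos in insertions:
            fh.write(f"{chrom}\t{pos}\n")
    paths["insertions_tsv"] = str(outdir / "insertions.tsv")

    cfg = {
        "probe_tracks": [Path(p).name for p in track_paths],
        "feature_gff": "features.gff",
        "rates_tsv": "rates.tsv",
        "fasta": "genome.fa",
        "pwm_file": "pwms.txt",
        "outdir": str(outdir / "results"),
        "seed": config.seed,
        # miniature-scale motif settings so the demo stays seconds-scale
        "motif": {"n_rand": 200, "n_background": 2000},
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    paths["config"] = str(outdir / "config.yaml")
    return paths
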