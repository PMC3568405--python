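"""End-to-end orchestration: normalize -> detect (x2) -> intersect ->
merge -> annotate -> profile -> motif-test, from a single config.

Every stage is the library function; this module only wires them, logs the
parameters actually used, and writes the artifacts. Identical config and
seed give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import chisq, consensus, hmm, io, metagene, motif

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "probe_tracks": [],
    "feature_gff": None,
    "rates_tsv": None,
    "fasta": None,
    "pwm_file": None,
    "outdir": "chiptile_out",
    "seed": 0,
    "log_level": "INFO",
    "scan": {
        "window_sizes_bp": [600, 800, 1000],
        "threshold_percentile": 0.95,
        "p_cutoff": 1e-4,
        "combine_rule": "intersection",
        "max_gap_probes": 2,
    },
    "hmm": {"tol": 1e-4, "max_iter": 100, "min_run": 3},
    "merge": {
        "max_midpoint_distance_bp": 125,
        "min_replicate_support": 2,
        "trimmed_width_bp": 250,
    },
    "proximity_bp": 125,
    "metagene": {"n_bins": 50, "flank_bp": 250},
    "motif": {"n_rand": 1000, "n_background": 10000, "fragment_bp": 250,
              "background_chromosomes": None},
}


@dataclass
class PipelineConfig:
    probe_tracks: list[str]
    feature_gff: str | None
    rates_tsv: str | None
    fasta: str | None
    pwm_file: str | None
    outdir: str
    seed: int
    log_level: str
    scan: chisq.ScanParams
    hmm: dict
    merge: consensus.MergeParams
    proximity_bp: int
    metagene: dict
    motif: dict


def _merge_defaults(user: dict, defaults: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_defaults(value, defaults[key], f"{path}{key}.")
        else:
            out[key] = value
    return out


def normalize_config(raw: dict) -> PipelineConfig:
    """Fill defaults, reject unknown keys and contradictory settings."""
    merged = _merge_defaults(raw or {}, _DEFAULTS)
    if len(merged["probe_tracks"]) < 2:
        raise ValueError(
            "need >= 2 replicate probe tracks: the consensus stage merges "
            "peaks supported by at least two replicates"
        )
    if merged["proximity_bp"] <= 0:
        raise ValueError("proximity_bp must be > 0")
    if merged["merge"]["min_replicate_support"] < 2:
        warnings.warn(
            "min_replicate_support < 2 departs from the >= 2-replicate "
            "consensus rule", stacklevel=2,
        )
    scan = merged["scan"]
    return PipelineConfig(
        probe_tracks=list(merged["probe_tracks"]),
        feature_gff=merged["feature_gff"],
        rates_tsv=merged["rates_tsv"],
        fasta=merged["fasta"],
        pwm_file=merged["pwm_file"],
        outdir=merged["outdir"],
        seed=int(merged["seed"]),
        log_level=merged["log_level"],
        scan=chisq.ScanParams(
            window_sizes_bp=tuple(scan["window_sizes_bp"]),
            threshold_percentile=scan["threshold_percentile"],
            p_cutoff=scan["p_cutoff"],
            combine_rule=scan["combine_rule"],
            max_gap_probes=scan["max_gap_probes"],
        ),
        hmm=dict(merged["hmm"]),
        merge=consensus.MergeParams(**merged["merge"]),
        proximity_bp=int(merged["proximity_bp"]),
        metagene=dict(merged["metagene"]),
        motif=dict(merged["motif"]),
    )


def validate_config(path) -> PipelineConfig:
    """Load and normalize a YAML pipeline config; paths checked to exist."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = normalize_config(raw)
    base = Path(path).parent
    def resolve(p):
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)
    cfg.probe_tracks = [resolve(p) for p in cfg.probe_tracks]
    cfg.feature_gff = resolve(cfg.feature_gff)
    cfg.rates_tsv = resolve(cfg.rates_tsv)
    cfg.fasta = resolve(cfg.fasta)
    cfg.pwm_file = resolve(cfg.pwm_file)
    for p in cfg.probe_tracks + [cfg.feature_gff, cfg.rates_tsv, cfg.fasta, cfg.pwm_file]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(p)
    return cfg


def call_peaks(replicates, scan_params, hmm_settings, merge_params):
    """Detect with both methods per replicate, intersect, and merge.

    ``replicates`` is a list of {chromosome: ProbeTrack} of *normalized*
    tracks. Returns (peaks, per-replicate intersected regions, hmm models).
    """
    per_rep_regions = []
    models = []
    for rep_id, tracks in enumerate(replicates):
        chisq_regions = chisq.scan_replicate(tracks, scan_params, replicate=rep_id)
        model, hmm_regions = hmm.segment_replicate(
            tracks, tol=hmm_settings.get("tol", 1e-4),
            max_iter=hmm_settings.get("max_iter", 100),
            min_run=hmm_settings.get("min_run", 3), replicate=rep_id,
        )
        common = consensus.intersect_detectors(chisq_regions, hmm_regions)
        logger.info(
            "replicate %d: %d chisq regions, %d hmm regions, %d common",
            rep_id, len(chisq_regions), len(hmm_regions), len(common),
        )
        per_rep_regions.append(common)
        models.append(model)
    peaks = consensus.merge_replicates(per_rep_regions, merge_params)
    return peaks, per_rep_regions, models


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole analysis; returns a manifest of written artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    raw_replicates = [io.read_probe_track(p) for p in cfg.probe_tracks]
    replicates = [io.normalize_replicate(tracks) for tracks in raw_replicates]

    peaks, per_rep, models = call_peaks(replicates, cfg.scan, cfg.hmm, cfg.merge)
    peaks_path = outdir / "peaks.gff"
    io.write_peaks_gff(peaks, peaks_path)
    manifest["peaks_gff"] = str(peaks_path)
    io.write_json([m.to_dict() for m in models], outdir / "hmm_models.json")
    manifest["hmm_models"] = str(outdir / "hmm_models.json")

    features = None
    assignments = None
    if cfg.feature_gff:
        features = io.read_feature_gff(cfg.feature_gff)
        assignments = ann.assign_peaks(peaks, features, cfg.proximity_bp)
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write("peak\tchrom\tmidpoint\tfeature\tclass\tdistance\n")
            for a in assignments:
                fh.write(f"{a.peak_name}\t{a.chromosome}\t{a.midpoint}\t"
                         f"{a.feature}\t{a.feature_class}\t{a.distance}\n")
        manifest["assignments_tsv"] = str(outdir / "assignments.tsv")
        summary = {
            "n_peaks": len(peaks),
            "composition": ann.class_composition(assignments) if assignments else {},
            "fraction_bound_percent": ann.fraction_bound(assignments, features),
        }
        io.write_json(summary, outdir / "occupancy_summary.json")
        manifest["occupancy_summary"] = str(outdir / "occupancy_summary.json")

        signal = metagene.average_tracks(replicates)
        mg = cfg.metagene
        orfs = features.by_class("ORF")
        if len(orfs):
            profile = metagene.average_profile(
                signal, orfs, n_bins=mg["n_bins"], flank_bp=mg["flank_bp"], label="ORF_all")
            profile.to_tsv(outdir / "metagene_ORF_all.tsv")
            manifest["metagene_ORF_all"] = str(outdir / "metagene_ORF_all.tsv")
        tdnas = features.by_class("tRNA_gene")
        bound_tdnas = None
        if len(tdnas) and assignments:
            try:
                bound_tdnas = metagene.bound_subset_profile(
                    signal, tdnas, assignments, n_bins=mg["n_bins"],
                    flank_bp=mg["flank_bp"], label="tRNA_gene_bound")
                bound_tdnas.to_tsv(outdir / "metagene_tRNA_bound.tsv")
                manifest["metagene_tRNA_bound"] = str(outdir / "metagene_tRNA_bound.tsv")
            except ValueError:
                logger.info("no bound tRNA genes; tDNA profile skipped")
        if cfg.rates_tsv:
            rates = io.read_rates_tsv(cfg.rates_tsv)
            classes = metagene.classify_by_rate(orfs, rates)
            for label in ("high", "medium", "low"):
                subset = classes[label]
                if not len(subset):
                    continue
                prof = metagene.average_profile(
                    signal, subset, n_bins=mg["n_bins"], flank_bp=mg["flank_bp"],
                    label=f"ORF_{label}")
                prof.to_tsv(outdir / f"metagene_ORF_{label}.tsv")
                manifest[f"metagene_ORF_{label}"] = str(outdir / f"metagene_ORF_{label}.tsv")
        else:
            logger.info("no rates table given; rate-stratified profiles skipped")

    if cfg.fasta and cfg.pwm_file:
        genome = motif.read_fasta(cfg.fasta)
        pwms = motif.read_jaspar_pfms(cfg.pwm_file)
        seqs = motif.extract_peak_sequences(genome, peaks)
        mo = cfg.motif
        background = motif.background_fragments(
            genome, n=mo["n_background"], size_bp=mo["fragment_bp"],
            chromosomes=mo["background_chromosomes"], seed=cfg.seed,
        )
        with open(outdir / "motif_enrichment.tsv", "w") as fh:
            fh.write("pwm\tobserved\tnull_mean\tnull_sd\tp_value\tn_sequences\n")
            for i, pwm in enumerate(pwms):
                res = motif.empirical_pvalue(
                    pwm, seqs, background, n_rand=mo["n_rand"],
                    seed=cfg.seed * 10_000 + i + 1,
                )
                fh.write(f"{res.pwm_name}\t{res.observed:.6g}\t{res.null_mean:.6g}\t"
                         f"{res.null_sd:.6g}\t{res.p_value:.6g}\t{res.n_peak_sequences}\n")
        manifest["motif_enrichment"] = str(outdir / "motif_enrichment.tsv")
    elif cfg.fasta or cfg.pwm_file:
        logger.info("motif stage needs both fasta and pwm_file; skipped")

    run_log = {
        "seed": cfg.seed,
        "scan": dataclasses.asdict(cfg.scan),
        "hmm": cfg.hmm,
        "merge": dataclasses.asdict(cfg.merge),
        "proximity_bp": cfg.proximity_bp,
        "metagene": cfg.metagene,
        "motif": cfg.motif,
        "inputs": {
            "probe_tracks": cfg.probe_tracks,
            "feature_gff": cfg.feature_gff,
            "rates_tsv": cfg.rates_tsv,
            "fasta": cfg.fasta,
            "pwm_file": cfg.pwm_file,
        },
        "n_peaks": len(peaks),
        "artifacts": manifest,
    }
    io.write_json(run_log, outdir / "run_log.json")
    manifest["run_log"] = str(outdir / "run_log.json")
    return manifest


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
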