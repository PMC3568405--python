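"""Readers and writers for on-disk formats, plus per-array biweight normalization.

Formats handled:

* probe tracks — tab-text (``chrom<TAB>position<TAB>log2_ratio``) or a
  probe-GFF dialect (one 9-column row per probe, score column = ratio);
* feature annotation — SGD-dump-style GFF3, types mapped to the package's
  feature classes via a configurable mapping table;
* consensus peaks — 9-column GFF with support in the score column and the
  peak id/midpoint in the attributes column;
* transcription rates — 2-column TSV (gene, mRNAs/hr).

All on-disk coordinates are 1-based inclusive (GFF convention).
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .core import Feature, FeatureTable, Peak, ProbeTrack

logger = logging.getLogger(__name__)

#: GFF type -> feature_class mapping applied by :func:`read_feature_gff`.
#: SGD dumps use "gene" for protein-coding loci; anything unmapped lands in
#: "other" so nothing is silently dropped.
DEFAULT_TYPE_MAP = {
    "ORF": "ORF",
    "gene": "ORF",
    "CDS": "ORF",
    "tRNA_gene": "tRNA_gene",
    "tRNA": "tRNA_gene",
    "snoRNA_gene": "snoRNA_gene",
    "snoRNA": "snoRNA_gene",
    "snRNA_gene": "snRNA_gene",
    "snRNA": "snRNA_gene",
    "ncRNA_gene": "ncRNA_gene",
    "ncRNA": "ncRNA_gene",
    "ARS": "ARS",
    "ARS_consensus_sequence": "ARS",
}


class ParseError(ValueError):
    """Malformed record in an input file; message names the file line."""


# ---------------------------------------------------------------------------
# probe tracks


def read_probe_track(path, dialect: str = "tab-text") -> dict[str, ProbeTrack]:
    """Read per-probe ratios into one ProbeTrack per chromosome.

    Records may appear in any order; they are sorted by position per
    chromosome. A duplicated position on a chromosome is rejected.
    """
    if dialect not in ("tab-text", "probe-gff"):
        raise ValueError(f"unknown probe-track dialect: {dialect!r}")
    path = Path(path)
    chroms: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "tab-text":
                    if len(parts) != 3:
                        raise ValueError(f"expected 3 tab-separated columns, got {len(parts)}")
                    chrom, pos, val = parts[0], int(parts[1]), float(parts[2])
                else:
                    if len(parts) != 9:
                        raise ValueError(f"expected 9 GFF columns, got {len(parts)}")
                    chrom, pos, val = parts[0], int(parts[3]), float(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            chroms.setdefault(chrom, []).append((pos, val))
    tracks: dict[str, ProbeTrack] = {}
    for chrom, records in chroms.items():
        records.sort()
        positions = np.array([p for p, _ in records], dtype=np.int64)
        dup = np.where(np.diff(positions) == 0)[0]
        if dup.size:
            raise ParseError(
                f"{path}: duplicate probe position {int(positions[dup[0]])} on {chrom}"
            )
        values = np.array([v for _, v in records], dtype=np.float64)
        tracks[chrom] = ProbeTrack(chrom, positions, values)
    return tracks


def write_probe_track(tracks: dict[str, ProbeTrack], path, dialect: str = "tab-text") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for pos, val in zip(t.positions, t.values):
                if dialect == "tab-text":
                    fh.write(f"{chrom}\t{pos}\t{val:.9g}\n")
                elif dialect == "probe-gff":
                    fh.write(f"{chrom}\tchiptile\tprobe\t{pos}\t{pos}\t{val:.9g}\t.\t.\t.\n")
                else:
                    raise ValueError(f"unknown probe-track dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# feature GFF


def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
        elif " " in chunk:  # GFF2-style `key value`
            k, v = chunk.split(None, 1)
        else:
            k, v = chunk, ""
        attrs[k.strip()] = v.strip().strip('"')
    return attrs


def read_feature_gff(path, type_map: dict[str, str] | None = None) -> FeatureTable:
    """Read an SGD-style feature GFF into a FeatureTable.

    ``type_map`` maps the GFF type column to a feature class; unmapped types
    are collected under "other". Per-class counts are logged.
    """
    type_map = DEFAULT_TYPE_MAP if type_map is None else type_map
    path = Path(path)
    features: list[Feature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns, got {len(parts)}")
            chrom, _source, gff_type, start_s, end_s, _score, strand, _frame, attrs_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ParseError(
                    f"{path}:{lineno}: end {end} < start {start}"
                )
            attrs = _parse_attributes(attrs_s)
            name = attrs.get("ID") or attrs.get("Name") or attrs.get("gene") or f"feat_{lineno}"
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate feature name {name}")
            seen.add(name)
            fclass = type_map.get(gff_type, "other")
            features.append(Feature(name, chrom, start, end, strand if strand in "+-" else ".", fclass))
    table = FeatureTable(features)
    logger.info("read %d features from %s: %s", len(table), path, table.class_counts())
    return table


def write_feature_gff(table: FeatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table:
            fh.write(
                f"{f.chromosome}\tchiptile\t{f.feature_class}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\tID={f.name}\n"
            )


# ---------------------------------------------------------------------------
# peak GFF (supplementary-table layout: 9 columns, score = replicate support)


def write_peaks_gff(peaks: list[Peak], path) -> None:
    """Write consensus peaks as 9-column GFF, one row per 250 bp site."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, p in enumerate(peaks, 1):
            name = p.name or f"peak_{i:04d}"
            fh.write(
                f"{p.chromosome}\tchiptile\tbinding_site\t{p.start}\t{p.end}"
                f"\t{p.support}\t.\t.\tID={name};midpoint={p.midpoint}\n"
            )


def read_peaks_gff(path) -> list[Peak]:
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns, got {len(parts)}")
            chrom, _src, _type, start_s, end_s, score_s, _strand, _frame, attrs_s = parts
            try:
                start, end = int(start_s), int(end_s)
                support = int(float(score_s))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinate or score") from exc
            attrs = _parse_attributes(attrs_s)
            midpoint = int(attrs["midpoint"]) if "midpoint" in attrs else (start + end) // 2
            peaks.append(
                Peak(chrom, start, end, midpoint=midpoint, support=support,
                     name=attrs.get("ID", f"peak_{lineno}"))
            )
    return peaks


# ---------------------------------------------------------------------------
# detector-region GFF (intermediate artifact between detect and merge)


def write_regions_gff(regions, path) -> None:
    from .core import Region  # local import to keep module load order simple

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(regions, 1):
            rep = "." if r.replicate is None else str(r.replicate)
            fh.write(
                f"{r.chromosome}\t{r.source or 'chiptile'}\tregion\t{r.start}\t{r.end}"
                f"\t{r.score:.6g}\t.\t.\tID=region_{i:05d};replicate={rep}\n"
            )


def read_regions_gff(path):
    from .core import Region

    path = Path(path)
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns, got {len(parts)}")
            attrs = _parse_attributes(parts[8])
            rep = attrs.get("replicate", ".")
            regions.append(
                Region(
                    chromosome=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    score=float(parts[5]),
                    source=parts[1],
                    replicate=None if rep == "." else int(rep),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# rates and truth


def read_rates_tsv(path) -> dict[str, float]:
    """Read a gene -> transcription rate (mRNAs/hr) table."""
    rates: dict[str, float] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                rate = float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric rate") from exc
            if rate < 0:
                raise ParseError(f"{path}:{lineno}: negative rate {rate}")
            rates[parts[0]] = rate
    return rates


def write_rates_tsv(rates: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(rates):
            fh.write(f"{gene}\t{rates[gene]:.6g}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# biweight normalization


def biweight_location(values: np.ndarray, c: float = 5.0, tol: float = 1e-6,
                      max_iter: int = 100) -> float:
    """Iterated Tukey biweight location estimate.

    Starting from the median m, probes are weighted w_i = (1 - u_i^2)^2 for
    u_i = (x_i - m) / (c * MAD) with |u_i| < 1 (0 outside), and m is updated
    to the weighted mean until it moves by less than ``tol``. When MAD = 0
    the estimate degenerates to the median (warned).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("biweight location needs >= 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        warnings.warn("MAD is zero; falling back to median centering", stacklevel=2)
        return m
    for _ in range(max_iter):
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        sw = w.sum()
        if sw == 0.0:  # unreachable with m inside the data range; guard anyway
            warnings.warn("all biweight weights zero; keeping median", stacklevel=2)
            return m
        m_new = float((w * x).sum() / sw)
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def biweight_normalize(values: np.ndarray, c: float = 5.0, tol: float = 1e-6,
                       max_iter: int = 100) -> np.ndarray:
    """Center log ratios by subtracting the Tukey biweight location."""
    x = np.asarray(values, dtype=np.float64)
    return x - biweight_location(x, c=c, tol=tol, max_iter=max_iter)


def normalize_replicate(tracks: dict[str, ProbeTrack], c: float = 5.0,
                        tol: float = 1e-6, max_iter: int = 100) -> dict[str, ProbeTrack]:
    """Per-array normalization: one biweight location over all chromosomes pooled."""
    pooled = np.concatenate([t.values for t in tracks.values()])
    m = biweight_location(pooled, c=c, tol=tol, max_iter=max_iter)
    return {
        chrom: ProbeTrack(chrom, t.positions.copy(), t.values - m)
        for chrom, t in tracks.items()
    }
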