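"""Readers and writers for the flat-text formats the pipeline touches.

Segment tables, variant tables, expression matrices and the cohort
table are plain TSV; gene sets are standard GMT; exome targets are
standard BED (0-based half-open, converted on read); mutation catalogs
and signature references are 96-row TSVs in the package's documented
channel order. Every reader enforces the corresponding type invariants
and raises an error naming the offending row.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model import (
    CALLER_UNIVERSE,
    CHANNELS,
    CohortRecord,
    ExpressionMatrix,
    GeneSetCollection,
    MutationCatalog,
    Segment,
    SegmentProfile,
    SignatureMatrix,
    validate_variant_table,
)

__all__ = [
    "read_segments",
    "write_segments",
    "read_variants",
    "write_variants",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_target_size",
    "read_cohort",
    "write_cohort",
    "bundled_cohort",
    "read_catalog",
    "write_catalog",
    "read_signature_matrix",
    "write_signature_matrix",
]

PathLike = Union[str, Path]


# -- allele-specific copy-number segments ---------------------------------

_SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "major_cn", "minor_cn"]


def read_segments(path: PathLike) -> dict[str, SegmentProfile]:
    """Read a SEG-like TSV into per-sample :class:`SegmentProfile` maps."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in _SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: segment table missing columns {missing}")
    profiles: dict[str, SegmentProfile] = {}
    for sample, group in df.groupby("sample", sort=False):
        segments = []
        for i, row in group.iterrows():
            major, minor = int(row["major_cn"]), int(row["minor_cn"])
            if major + minor != int(row["total_cn"]):
                raise ValueError(
                    f"{path} row {i} (sample {sample}): total_cn "
                    f"{row['total_cn']} != major_cn + minor_cn"
                )
            try:
                segments.append(
                    Segment(
                        chromosome=str(row["chrom"]),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        major_cn=major,
                        minor_cn=minor,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} row {i} (sample {sample}): {exc}") from exc
        profiles[str(sample)] = SegmentProfile(str(sample), segments)
    return profiles


def write_segments(profiles: dict[str, SegmentProfile], path: PathLike) -> None:
    rows = []
    for sample, profile in profiles.items():
        for seg in profile.segments:
            rows.append(
                {
                    "sample": sample,
                    "chrom": seg.chromosome,
                    "start": seg.start,
                    "end": seg.end,
                    "total_cn": seg.total_cn,
                    "major_cn": seg.major_cn,
                    "minor_cn": seg.minor_cn,
                }
            )
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# -- somatic variant tables ------------------------------------------------


def read_variants(path: PathLike) -> pd.DataFrame:
    """Read a MAF-like variant TSV; callers are semicolon-joined names."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chromosome": str, "ref": str, "alt": str, "gene": str},
        keep_default_na=False,
    )
    if len(df) == 0:
        df = df.reindex(
            columns=[
                "chromosome", "position", "ref", "alt", "gene",
                "consequence_class", "depth", "alt_reads", "vaf",
                "callers", "trinucleotide_context",
            ]
        )
        df["callers"] = df["callers"].astype(object)
        return df
    df["position"] = df["position"].astype(int)
    df["depth"] = df["depth"].astype(int)
    df["alt_reads"] = df["alt_reads"].astype(int)
    df["vaf"] = df["vaf"].astype(float)
    df["callers"] = [
        frozenset(c.split(";")) if c else frozenset() for c in df["callers"].astype(str)
    ]
    if "trinucleotide_context" not in df.columns:
        df["trinucleotide_context"] = None
    else:
        df["trinucleotide_context"] = [
            c if c else None for c in df["trinucleotide_context"].astype(str)
        ]
    validate_variant_table(df, caller_universe=CALLER_UNIVERSE)
    return df


def write_variants(df: pd.DataFrame, path: PathLike) -> None:
    out = df.copy()
    out["callers"] = [";".join(sorted(c)) for c in out["callers"]]
    out["trinucleotide_context"] = [
        c if c is not None else "" for c in out["trinucleotide_context"]
    ]
    out.to_csv(path, sep="\t", index=False)


# -- expression ------------------------------------------------------------


def read_expression(
    path: PathLike,
    scale: str = "log2tpm",
    gene_lengths: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric values in column {non_numeric[0]!r}")
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(values=df, scale=scale, gene_lengths=gene_lengths)


def write_expression(matrix: ExpressionMatrix, path: PathLike) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# -- gene sets (GMT) -------------------------------------------------------


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a standard GMT file (name, description, tab-separated members)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path} line {lineno}: GMT lines need name, description "
                    f"and at least one member ({len(fields)} fields found)"
                )
            name = fields[0]
            members = [g for g in fields[2:] if g]
            sets[name] = list(dict.fromkeys(members))
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, collection.provenance or "na"] + members) + "\n")


# -- exome targets (BED) ---------------------------------------------------


def read_target_size(path: PathLike) -> float:
    """Total unique targeted length in Mb from a BED file.

    BED is 0-based half-open; overlapping intervals are merged before
    summing, so splitting or re-ordering intervals never changes the
    answer.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"{path} line {lineno}: end ({end}) <= start ({start})"
                )
            intervals.setdefault(chrom, []).append((start, end))
    total_bp = 0
    for chrom_intervals in intervals.values():
        chrom_intervals.sort()
        cur_start, cur_end = chrom_intervals[0]
        for start, end in chrom_intervals[1:]:
            if start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                total_bp += cur_end - cur_start
                cur_start, cur_end = start, end
        total_bp += cur_end - cur_start
    return total_bp / 1e6


# -- cohort table ----------------------------------------------------------

_COHORT_COLUMNS = [
    "sample_id", "germline_gene", "er_status", "tp53", "rcb",
    "tnbc_subtype", "mutations_per_mb", "purity", "ploidy", "analyzed",
]


def read_cohort(path: PathLike) -> list[CohortRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        if not row["germline_gene"]:
            raise ValueError(f"{path} row {i}: missing germline gene")
        try:
            records.append(
                CohortRecord(
                    sample_id=row["sample_id"],
                    germline_gene=row["germline_gene"],
                    er_status=row["er_status"],
                    tp53=row["tp53"],
                    rcb=row["rcb"],
                    tnbc_subtype=row["tnbc_subtype"],
                    mutations_per_mb=float(row["mutations_per_mb"]),
                    purity=float(row["purity"]),
                    ploidy=float(row["ploidy"]),
                    analyzed=bool(int(row["analyzed"])),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
    return records


def write_cohort(records: list[CohortRecord], path: PathLike) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "germline_gene": r.germline_gene,
            "er_status": r.er_status,
            "tp53": r.tp53,
            "rcb": r.rcb,
            "tnbc_subtype": r.tnbc_subtype,
            "mutations_per_mb": r.mutations_per_mb,
            "purity": r.purity,
            "ploidy": r.ploidy,
            "analyzed": int(r.analyzed),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def bundled_cohort() -> list[CohortRecord]:
    """The bundled clinical-table transcription (13 analyzed + 5 excluded)."""
    ref = resources.files("parpomics.data").joinpath("table1_cohort.tsv")
    with resources.as_file(ref) as path:
        return read_cohort(path)


# -- catalogs and signature references -------------------------------------


def write_catalog(catalog: MutationCatalog, path: PathLike) -> None:
    """Write a catalog as a 96-row TSV in the documented channel order."""
    series = catalog.to_series()
    df = pd.DataFrame({"channel": series.index, "count": series.values})
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: PathLike, sample_id: str = "") -> MutationCatalog:
    df = pd.read_csv(path, sep="\t")
    if list(df["channel"]) != list(CHANNELS):
        raise ValueError(f"{path}: channels missing or out of order")
    return MutationCatalog(df["count"].to_numpy(), sample_id=sample_id)


def read_signature_matrix(path: PathLike) -> SignatureMatrix:
    """Read a COSMIC-v2-style signature TSV (channel, sig1, sig2, ...)."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df = df.set_index(first)
    if list(df.index) != list(CHANNELS):
        raise ValueError(f"{path}: channel column missing or out of order")
    return SignatureMatrix(list(df.columns), df.to_numpy().T)


def write_signature_matrix(signatures: SignatureMatrix, path: PathLike) -> None:
    frame = signatures.to_frame()
    frame.index.name = "channel"
    frame.to_csv(path, sep="\t")
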