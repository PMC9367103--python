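"""Readers and writers for the pipeline's tabular interfaces.

Mutation tables are TSV (columns: patient_id, timepoint, chrom, pos
[1-based], ref, alt, gene, effect, alt_reads, ref_reads) or minimal
VCF 4.2 with an AD FORMAT field (ref,alt depths) and GENE/EFFECT INFO
keys.  Segment tables are BED-like TSV (0-based half-open) with
major/minor tumor copy number; purity and clinical-measurement tables
are plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

__all__ = [
    "MUTATION_COLUMNS",
    "SEGMENT_COLUMNS",
    "read_mutation_table",
    "read_segments",
    "read_purity",
    "read_measurements",
]

MUTATION_COLUMNS = ["patient_id", "timepoint", "chrom", "pos", "ref", "alt",
                    "gene", "effect", "alt_reads", "ref_reads"]
SEGMENT_COLUMNS = ["patient_id", "timepoint", "chrom", "start", "end",
                   "n_major", "n_minor"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A row failed validation; the message carries 1-based line numbers."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ParseError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        if vals.isna().any():
            lines = [int(i) + 2 for i in df.index[vals.isna()][:5]]
            raise ParseError(f"{path}: missing {col!r} at line(s) {lines}")
        df[col] = vals.astype(int)
    return df


def _add_mutation_id(df: pd.DataFrame) -> pd.DataFrame:
    if "mutation_id" not in df.columns:
        df["mutation_id"] = (
            df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"].astype(str) + ">" + df["alt"].astype(str)
        )
    return df


def _read_mutation_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, MUTATION_COLUMNS, path)
    df = _numeric(df, ["pos", "alt_reads", "ref_reads"], path)
    if (df[["alt_reads", "ref_reads"]] < 0).any().any():
        raise ParseError(f"{path}: negative read counts")
    return _add_mutation_id(df)


def _read_mutation_vcf(path: Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise SchemaError(f"{path}: expected exactly one sample, got {samples}")
        sample = samples[0]
        patient_id, _, timepoint = sample.rpartition(".")
        for rec in vcf:
            ad = rec.samples[sample].get("AD")
            if ad is None or len(ad) < 2:
                raise SchemaError(f"{path}: AD FORMAT field required")
            rows.append(
                dict(
                    patient_id=patient_id or sample,
                    timepoint=timepoint,
                    chrom=rec.chrom,
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    gene=str(rec.info.get("GENE", "")),
                    effect=str(rec.info.get("EFFECT", "")),
                    alt_reads=int(ad[1]),
                    ref_reads=int(ad[0]),
                    mutation_id=rec.id
                    or f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alts[0]}",
                )
            )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS + ["mutation_id"])


def read_mutation_table(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read one mutation table (TSV or minimal VCF) with validation.

    Returns a DataFrame with :data:`MUTATION_COLUMNS` plus
    ``mutation_id`` (derived from locus and alleles when absent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix in (".vcf", ".bcf") else "tsv"
    if dialect == "tsv":
        return _read_mutation_tsv(path)
    if dialect == "vcf":
        return _read_mutation_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_segments(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SEGMENT_COLUMNS, path)
    df = _numeric(df, ["start", "end", "n_major", "n_minor"], path)
    if (df[["n_major", "n_minor"]] < 0).any().any():
        raise ParseError(f"{path}: negative copy numbers")
    return df


def read_purity(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["patient_id", "timepoint", "purity"], path)
    df["purity"] = pd.to_numeric(df["purity"], errors="raise").astype(float)
    if ((df["purity"] < 0) | (df["purity"] > 1)).any():
        raise ParseError(f"{path}: purity outside [0, 1]")
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Clinical diameters: patient_id, timepoint, largest_mm, perpendicular_mm."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ["patient_id", "timepoint", "largest_mm", "perpendicular_mm"], path
    )
    for col in ("largest_mm", "perpendicular_mm"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if (df[col] < 0).any():
            raise ParseError(f"{path}: negative diameter in {col!r}")
    return df
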