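"""Readers and writers for the delimited-text formats the pipeline consumes.

Matrices and tables travel as TSV/CSV, gene sets as GMT, and the tissue
atlas as a gene x tissue table of median expression values.  Readers
validate on ingest and normalise to the internal conventions (samples in
rows, upper-cased gene symbols).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    LOG2,
    RAW,
    AbundanceMatrix,
    AnalyteAnnotation,
    SampleMetadata,
    ValidationError,
)

SAMPLES_IN_ROWS = "samples_in_rows"
SAMPLES_IN_COLUMNS = "samples_in_columns"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_abundance_matrix(
    path,
    orientation: str = SAMPLES_IN_ROWS,
    scale: str = RAW,
    drop_incomplete_analytes: bool = False,
) -> AbundanceMatrix:
    """Read a delimited abundance matrix.

    ``orientation`` declares the layout on disk; the returned matrix always
    has samples in rows.  Missing values are rejected unless
    ``drop_incomplete_analytes`` is set, in which case analytes with any
    missing value are dropped (for data from other platforms; the SOMAscan
    matrix is complete).
    """
    if orientation not in (SAMPLES_IN_ROWS, SAMPLES_IN_COLUMNS):
        raise ValidationError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate ids in header of {path}: {dupes[:5]}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == SAMPLES_IN_COLUMNS:
        df = df.T
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ValidationError(
            f"non-numeric cells in columns {non_numeric[:5]} of {path}"
        )
    if df.isna().any().any():
        if drop_incomplete_analytes:
            df = df.dropna(axis=1)
        else:
            col = df.columns[df.isna().any()][0]
            row = df.index[df[col].isna()][0]
            raise ValidationError(
                f"missing value at sample {row!r}, analyte {col!r} in {path}"
            )
    return AbundanceMatrix(df, scale=scale)


def write_abundance_matrix(matrix: AbundanceMatrix, path) -> None:
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_sample_metadata(path, strict: bool = False) -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return SampleMetadata(df, strict=strict)


def write_sample_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_analyte_annotation(path) -> AnalyteAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].astype(bool)
    if "dilution_bin" in df.columns:
        df["dilution_bin"] = df["dilution_bin"].astype("Int64")
    return AnalyteAnnotation(df)


def write_analyte_annotation(annotation: AnalyteAnnotation, path) -> None:
    df = annotation.table.copy()
    df["gene_symbols"] = df["gene_symbols"].apply(" ".join)
    df.to_csv(path, sep=_sep_for(path), index_label="analyte_id")


def read_gene_sets(path) -> dict[str, dict]:
    """Read a GMT gene-set collection.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Gene
    symbols are upper-cased and de-duplicated within a set (order kept).
    Lines with fewer than three fields (no genes) are rejected.
    """
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has fewer than 3 fields"
                )
            term_id, term_name, *genes = parts
            seen, ordered = set(), []
            for g in genes:
                g = g.strip().upper()
                if g and g not in seen:
                    seen.add(g)
                    ordered.append(g)
            if not ordered:
                raise ValidationError(f"{path}:{lineno}: gene set {term_id!r} is empty")
            if term_id in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term {term_id!r}")
            sets[term_id] = {"term_name": term_name, "genes": ordered}
    return sets


def write_gene_sets(gene_sets: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for term_id, rec in gene_sets.items():
            fh.write(
                "\t".join([term_id, rec.get("term_name", "")] + list(rec["genes"]))
                + "\n"
            )


def read_tissue_atlas(path) -> pd.DataFrame:
    """Read a gene x tissue table of median expression values.

    Gene symbols are upper-cased; duplicate gene rows are collapsed by the
    per-tissue median.  Values must be nonnegative.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"tissue atlas {path} has no tissue columns")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"negative expression values in tissue atlas {path}")
    df.index = df.index.astype(str).str.upper()
    if df.index.has_duplicates:
        df = df.groupby(level=0).median()
    return df


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep=_sep_for(path), index_label=index_label)


def read_prior_study(path) -> pd.DataFrame:
    """Read an external differential table: gene, log2_fc, significant."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in ("gene", "log2_fc", "significant") if c not in df.columns]
    if missing:
        raise ValidationError(f"prior study table missing columns {missing}")
    df = df.copy()
    df["gene"] = df["gene"].astype(str).str.upper()
    if df["gene"].duplicated().any():
        raise ValidationError("duplicate gene ids in prior study table")
    if not np.isfinite(df["log2_fc"]).all():
        raise ValidationError("non-finite log2_fc in prior study table")
    df["significant"] = df["significant"].astype(bool)
    return df.set_index("gene")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
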