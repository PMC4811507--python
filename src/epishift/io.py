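"""Readers and writers for the tabular dialects the pipeline touches.

* beta matrix: tab-delimited, first column ``probe_id``, one column per
  sample, values in [0, 1] or a missing token (``NA``, ``nan``, empty)
* gene models: BED6-like TSV (chrom, start, end, gene_id, score, strand)
* expression: tab-delimited, first column ``gene_id``, RPKM per sample
* sample sheet: CSV with sample_id, condition, genotype, cohort

All readers accept gzip-compressed files (by ``.gz`` suffix).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .genes import build_gene_table
from .intervals import _open_text

PathLike = Union[str, Path]

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_gene_models",
    "write_gene_models",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "NULL", "."}

CONDITIONS = ("reference", "perturbed")
GENOTYPES = ("WT", "MUT")


def read_beta_matrix(path: PathLike, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a probes x samples beta-value matrix.

    Values must lie in [0, 1]; anything outside is rejected with the
    offending row/column named.  Missing tokens become NaN.  When a probe
    *manifest* is given, every row's probe must appear in it and the
    returned matrix is reindexed to manifest order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe row: {dup}")
    mat = df.apply(lambda col: pd.to_numeric(
        col.where(~col.astype(str).str.strip().isin(_MISSING_TOKENS)),
        errors="coerce"))
    # cells that were neither missing nor numeric
    bad_nonnum = mat.isna() & ~df.isna() & ~df.astype(str).apply(
        lambda c: c.str.strip().isin(_MISSING_TOKENS))
    if bad_nonnum.to_numpy().any():
        r, c = np.argwhere(bad_nonnum.to_numpy())[0]
        raise ValueError(
            f"non-numeric beta value at probe {mat.index[r]!r}, "
            f"sample {mat.columns[c]!r}: {df.iloc[r, c]!r}")
    out_of_range = (mat < 0) | (mat > 1)
    if out_of_range.to_numpy().any():
        r, c = np.argwhere(out_of_range.to_numpy())[0]
        raise ValueError(
            f"beta value outside [0, 1] at probe {mat.index[r]!r}, "
            f"sample {mat.columns[c]!r}: {mat.iloc[r, c]}")
    mat = mat.astype(float)
    mat.index.name = "probe_id"
    if manifest is not None:
        unknown = mat.index.difference(manifest["probe_id"])
        if len(unknown):
            raise ValueError(f"probe absent from manifest: {unknown[0]!r}")
        mat = mat.reindex(manifest["probe_id"])
    return mat


def write_beta_matrix(mat: pd.DataFrame, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        mat.to_csv(fh, sep="\t", float_format="%.6f", na_rep="NA",
                   index_label="probe_id")


def read_gene_models(path: PathLike, promoter_flank: int = 1500,
                     terminus_flank: int = 1500) -> pd.DataFrame:
    """Read BED6-like gene models and derive feature windows."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    return build_gene_table(
        df[["gene_id", "chrom", "start", "end", "strand"]],
        promoter_flank=promoter_flank, terminus_flank=terminus_flank,
    )


def write_gene_models(genes: pd.DataFrame, path: PathLike) -> None:
    out = genes[["chrom", "start", "end", "gene_id", "strand"]].copy()
    out.insert(4, "score", 0)
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_expression(path: PathLike) -> pd.DataFrame:
    """Read a gene x sample RPKM table; values must be >= 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    mat = df.astype(float)
    if (mat < 0).to_numpy().any():
        r, c = np.argwhere((mat < 0).to_numpy())[0]
        raise ValueError(
            f"negative RPKM at gene {mat.index[r]!r}, sample {mat.columns[c]!r}")
    return mat


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        expr.to_csv(fh, sep="\t", float_format="%.4f", index_label="gene_id")


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Read the CSV sample sheet (sample_id, condition, genotype, cohort)."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "condition", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if "cohort" not in df.columns:
        df["cohort"] = "default"
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup}")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise ValueError(
            f"invalid condition: {df.loc[bad, 'condition'].iloc[0]!r}")
    bad = ~df["genotype"].isin(GENOTYPES)
    if bad.any():
        raise ValueError(
            f"invalid genotype: {df.loc[bad, 'genotype'].iloc[0]!r}")
    return df.set_index("sample_id", drop=False)


def write_sample_sheet(sheet: pd.DataFrame, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        sheet.reset_index(drop=True).to_csv(fh, index=False)
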