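"""Stranded gene models with derived promoter / body / 3'-terminus windows.

The array-annotation features used throughout the pipeline (promoter,
gene body, gene terminus, intergenic) are derived deterministically from
the gene span and strand:

* promoter  = TSS +/- ``promoter_flank`` bp (default 1,500)
* terminus  = TES +/- ``terminus_flank`` bp, clipped to the gene span on
  the inner side so that very short genes do not let the terminus window
  swallow the promoter
* body      = the gene span minus the promoter and terminus windows

Windows are half-open bp intervals on the same 0-based system as
:mod:`epishift.intervals`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import PeakSet

__all__ = [
    "PROMOTER_FLANK",
    "TERMINUS_FLANK",
    "build_gene_table",
    "gene_feature_windows",
    "feature_peaksets",
]

PROMOTER_FLANK = 1500
TERMINUS_FLANK = 1500

_REQUIRED = ["gene_id", "chrom", "start", "end", "strand"]


def build_gene_table(
    df: pd.DataFrame,
    promoter_flank: int = PROMOTER_FLANK,
    terminus_flank: int = TERMINUS_FLANK,
) -> pd.DataFrame:
    """Derive tss/tes and feature windows for a table of gene spans.

    Parameters
    ----------
    df
        Must contain ``gene_id, chrom, start, end, strand`` with BED
        half-open coordinates and strand in {"+", "-"}.

    Returns
    -------
    DataFrame indexed by ``gene_id`` with the input columns plus
    ``tss, tes, prom_start, prom_end, term_start, term_end,
    body_start, body_end`` (body may be empty: body_end <= body_start).
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id: {dup}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand value: {df.loc[bad, 'strand'].iloc[0]}")
    if (df["end"] <= df["start"]).any():
        raise ValueError("gene end must exceed start")

    out = df.copy()
    plus = (out["strand"] == "+").to_numpy()
    start = out["start"].to_numpy(np.int64)
    end = out["end"].to_numpy(np.int64)
    # TSS is the first transcribed bp, TES the last (inclusive bp positions)
    out["tss"] = np.where(plus, start, end - 1)
    out["tes"] = np.where(plus, end - 1, start)

    tss = out["tss"].to_numpy(np.int64)
    tes = out["tes"].to_numpy(np.int64)
    out["prom_start"] = np.maximum(tss - promoter_flank, 0)
    out["prom_end"] = tss + promoter_flank + 1

    # terminus window clipped on the gene-interior side to the gene span
    term_lo = np.maximum(tes - terminus_flank, 0)
    term_hi = tes + terminus_flank + 1
    inner_lo = np.where(plus, np.maximum(term_lo, start), term_lo)
    inner_hi = np.where(plus, term_hi, np.minimum(term_hi, end))
    out["term_start"] = inner_lo
    out["term_end"] = inner_hi

    # body: gene span minus the promoter and terminus windows; the
    # promoter sits at the TSS end, the terminus at the TES end
    prom_end = out["prom_end"].to_numpy(np.int64)
    prom_start = out["prom_start"].to_numpy(np.int64)
    term_start = out["term_start"].to_numpy(np.int64)
    term_end = out["term_end"].to_numpy(np.int64)
    body_lo = np.where(plus, prom_end, term_end)
    body_hi = np.where(plus, term_start, prom_start)
    body_lo = np.clip(body_lo, start, end)
    body_hi = np.clip(body_hi, start, end)
    out["body_start"] = body_lo
    out["body_end"] = np.maximum(body_hi, body_lo)
    return out.set_index("gene_id", drop=False)


def gene_feature_windows(genes: pd.DataFrame, feature: str) -> PeakSet:
    """The windows of one feature across all genes, as a PeakSet."""
    cols = {
        "promoter": ("prom_start", "prom_end"),
        "terminus": ("term_start", "term_end"),
        "body": ("body_start", "body_end"),
        "gene": ("start", "end"),
    }
    lo, hi = cols[feature]
    sub = genes[genes[hi] > genes[lo]]
    return PeakSet.from_arrays(
        sub["chrom"].to_numpy(), sub[lo].to_numpy(), sub[hi].to_numpy()
    )


def feature_peaksets(genes: pd.DataFrame) -> dict[str, PeakSet]:
    """Merged promoter/terminus/body window sets used for annotation."""
    return {f: gene_feature_windows(genes, f).merge()
            for f in ("promoter", "terminus", "body")}
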