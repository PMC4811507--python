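"""Probe manifest construction: genomic feature and enhancer-class labels.

Each CpG probe is a single bp position.  It receives exactly one feature
label by the precedence rule

    promoter > terminus > body > intergenic

(the precedence only matters for short genes whose windows overlap), and
one enhancer class from H3K4me1 / H3K27ac peak membership:

    k4me1_only | k4me1_k27ac | k27ac_only | none

Probes on chromosomes unknown to the gene models are labelled intergenic
with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genes import feature_peaksets
from .intervals import PeakSet

__all__ = ["annotate_probes", "FEATURES", "ENHANCER_CLASSES"]

FEATURES = ("promoter", "terminus", "body", "intergenic")
ENHANCER_CLASSES = ("k4me1_only", "k4me1_k27ac", "k27ac_only", "none")


def annotate_probes(
    positions: pd.DataFrame,
    genes: pd.DataFrame,
    k4me1_peaks: PeakSet | None = None,
    k27ac_peaks: PeakSet | None = None,
) -> pd.DataFrame:
    """Build the probe manifest.

    Parameters
    ----------
    positions
        DataFrame with columns ``probe_id, chrom, pos`` (0-based bp).
    genes
        Gene table from :func:`epishift.genes.build_gene_table`.
    k4me1_peaks, k27ac_peaks
        Optional enhancer-mark peak sets; omitted marks count as empty.

    Returns
    -------
    DataFrame with columns ``probe_id, chrom, pos, feature,
    enhancer_class, nearest_gene``, sorted by (chrom, pos).
    """
    if positions["probe_id"].duplicated().any():
        dup = positions.loc[positions["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id: {dup}")
    man = positions[["probe_id", "chrom", "pos"]].copy()
    man["chrom"] = man["chrom"].astype(str)
    man["pos"] = man["pos"].astype(np.int64)
    man = man.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    known = set(genes["chrom"].unique()) if len(genes) else set()
    unknown = ~man["chrom"].isin(known)
    if unknown.any() and known:
        warnings.warn(
            f"{int(unknown.sum())} probes on chromosomes without gene models; "
            "labelled intergenic", stacklevel=2)

    feature = np.full(len(man), "intergenic", dtype=object)
    if len(genes):
        windows = feature_peaksets(genes)
        # apply in reverse precedence so higher precedence overwrites
        for feat in ("body", "terminus", "promoter"):
            inside = windows[feat].contains_points(man["chrom"], man["pos"])
            feature[inside] = feat
    man["feature"] = feature

    k4 = (k4me1_peaks.contains_points(man["chrom"], man["pos"])
          if k4me1_peaks is not None and len(k4me1_peaks) else np.zeros(len(man), bool))
    k27 = (k27ac_peaks.contains_points(man["chrom"], man["pos"])
           if k27ac_peaks is not None and len(k27ac_peaks) else np.zeros(len(man), bool))
    enh = np.full(len(man), "none", dtype=object)
    enh[k4 & ~k27] = "k4me1_only"
    enh[k4 & k27] = "k4me1_k27ac"
    enh[~k4 & k27] = "k27ac_only"
    man["enhancer_class"] = enh

    man["nearest_gene"] = _nearest_gene(man, genes)
    return man


def _nearest_gene(man: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Gene with the closest span per probe (distance 0 inside a gene)."""
    out = np.full(len(man), "", dtype=object)
    if not len(genes):
        return out
    for chrom, sub in genes.groupby("chrom", sort=False):
        sel = (man["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        gs = sub.sort_values("start")
        starts = gs["start"].to_numpy()
        ends = gs["end"].to_numpy()
        ids = gs["gene_id"].to_numpy()
        pos = man.loc[sel, "pos"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        left = np.clip(i, 0, len(gs) - 1)
        right = np.clip(i + 1, 0, len(gs) - 1)
        d_left = np.where(pos < ends[left], 0, pos - ends[left] + 1)
        d_left = np.where(i < 0, np.iinfo(np.int64).max, d_left)
        d_right = np.maximum(starts[right] - pos, 0)
        d_right = np.where(i + 1 >= len(gs), np.iinfo(np.int64).max, d_right)
        pick = np.where(d_left <= d_right, left, right)
        out[sel] = ids[pick]
    return out
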