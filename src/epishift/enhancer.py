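"""Enhancer-state stratification and expression-tier integration.

Enhancer states are bp-level set algebra on two normal-tissue marks:
H3K4me1 alone marks poised enhancers, H3K4me1 + H3K27ac and H3K27ac
mark active ones.  Gene expression is stratified into two tiers (high /
low, zeros included in low) on reference-condition RPKM, and fold
changes use the pseudocount rule ``fc = (pert + 0.01) / (ref + 0.01)``
so that unexpressed genes cannot produce unbounded ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import FEATURES
from .intervals import PeakSet
from .k36 import fisher_ease

__all__ = [
    "EnhancerStateMap",
    "classify_enhancer_states",
    "gene_enhancer_labels",
    "enhancer_delta_beta",
    "expression_tiers",
    "expression_fold_change",
    "tier_epigenome_contingency",
    "DEFAULT_TIER_CUTOFF_RPKM",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_TIER_CUTOFF_RPKM = 1.0
DEFAULT_PSEUDOCOUNT = 0.01
STATES = ("k4me1_only", "k4me1_k27ac", "k27ac_only")


@dataclass
class EnhancerStateMap:
    """bp-level partition of the union of the two enhancer marks."""

    k4me1_only: PeakSet
    k4me1_k27ac: PeakSet
    k27ac_only: PeakSet

    def __getitem__(self, state: str) -> PeakSet:
        return getattr(self, state)

    def total_bp(self) -> int:
        return sum(self[s].total_bp() for s in STATES)


def classify_enhancer_states(k4me1: PeakSet, k27ac: PeakSet) -> EnhancerStateMap:
    """Partition K4me1 | K27ac bp into exclusive / shared intervals."""
    return EnhancerStateMap(
        k4me1_only=k4me1.subtract(k27ac),
        k4me1_k27ac=k4me1.intersect(k27ac),
        k27ac_only=k27ac.subtract(k4me1),
    )


def gene_enhancer_labels(genes: pd.DataFrame, state_map: EnhancerStateMap,
                         flank: int = 10_000) -> pd.Series:
    """One enhancer label per gene from states hitting span +/- flank.

    A gene intersected by all three state classes is ``all_classes``;
    otherwise the label reflects which marks are present: ``k4me1_only``
    (K4me1 but no K27ac bp), ``k27ac_only`` (the reverse), and
    ``k4me1_k27ac`` (both marks); genes touching no state are ``none``.
    """
    spans = PeakSet(pd.DataFrame({
        "Chromosome": genes["chrom"].to_numpy(),
        "Start": np.maximum(genes["start"].to_numpy() - flank, 0),
        "End": genes["end"].to_numpy() + flank,
        "gene_pos": np.arange(len(genes)),   # survives PeakSet sorting
    }))
    back = spans.df["gene_pos"].to_numpy()
    hits = {}
    for state in STATES:
        h = np.zeros(len(genes), dtype=bool)
        h[back] = spans.overlaps_intervals(state_map[state])
        hits[state] = h
    has_k4 = hits["k4me1_only"] | hits["k4me1_k27ac"]
    has_k27 = hits["k27ac_only"] | hits["k4me1_k27ac"]
    label = np.full(len(genes), "none", dtype=object)
    label[has_k4 & ~has_k27] = "k4me1_only"
    label[~has_k4 & has_k27] = "k27ac_only"
    label[has_k4 & has_k27] = "k4me1_k27ac"
    all3 = hits["k4me1_only"] & hits["k4me1_k27ac"] & hits["k27ac_only"]
    label[all3] = "all_classes"
    return pd.Series(label, index=genes.index, name="enhancer_label")


def enhancer_delta_beta(track: pd.DataFrame, state_map: EnhancerStateMap,
                        manifest: pd.DataFrame) -> pd.DataFrame:
    """Delta-beta summary per (enhancer state x genomic feature) cell.

    Probes are pooled per probe (not per peak); empty cells carry NaN
    summaries with n = 0.
    """
    man = manifest.set_index("probe_id")
    delta = track["delta"].reindex(man.index)
    rows = []
    for state in STATES:
        ps = state_map[state]
        inside = ps.contains_points(man["chrom"], man["pos"]) \
            if len(ps) else np.zeros(len(man), bool)
        for feat in FEATURES:
            sel = inside & (man["feature"] == feat).to_numpy()
            vals = delta[sel].dropna()
            rows.append({
                "state": state, "feature": feat, "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "q25": vals.quantile(0.25) if len(vals) else np.nan,
                "median": vals.median() if len(vals) else np.nan,
                "q75": vals.quantile(0.75) if len(vals) else np.nan,
            })
    return pd.DataFrame(rows)


def expression_tiers(expr: pd.DataFrame, sheet: pd.DataFrame,
                     cutoff_rpkm: float = DEFAULT_TIER_CUTOFF_RPKM) -> pd.Series:
    """High/low tier per gene from mean reference-condition RPKM.

    Genes with no expression (RPKM 0) belong to the low tier.  Tier
    assignment depends only on reference samples.
    """
    if cutoff_rpkm <= 0:
        raise ValueError("cutoff_rpkm must be positive")
    ref_cols = sheet.index[sheet["condition"] == "reference"]
    ref_mean = expr[list(ref_cols)].mean(axis=1)
    return pd.Series(np.where(ref_mean < cutoff_rpkm, "low", "high"),
                     index=expr.index, name="tier")


def expression_fold_change(expr: pd.DataFrame, sheet: pd.DataFrame,
                           pseudocount: float = DEFAULT_PSEUDOCOUNT,
                           fc_threshold: float = 2.0):
    """Fold change per gene with the pseudocount rule.

    ``fc = (mean_pert + c) / (mean_ref + c)``; up if fc >= threshold,
    down if fc <= 1/threshold.  Returns ``(up_ids, down_ids, fc_series)``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ref_cols = sheet.index[sheet["condition"] == "reference"]
    pert_cols = sheet.index[sheet["condition"] == "perturbed"]
    c = pseudocount
    fc = ((expr[list(pert_cols)].mean(axis=1) + c)
          / (expr[list(ref_cols)].mean(axis=1) + c)).rename("fold_change")
    up = list(fc.index[fc >= fc_threshold])
    down = list(fc.index[fc <= 1.0 / fc_threshold])
    return up, down, fc


def tier_epigenome_contingency(universe, set_a, set_b,
                               name_a: str = "a", name_b: str = "b",
                               alpha: float = 1e-3) -> dict:
    """2x2 contingency of two gene sets over one universe, with EASE p.

    Typical comparisons: (low tier & up-regulated) x (K36 gain), etc.
    Both sets must be subsets of the universe.  Returns the count table,
    one-tailed EASE overlap p, plain depletion p, the two-tailed Fisher
    p, and a significance label at ``alpha``.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    for name, s in ((name_a, set_a), (name_b, set_b)):
        if not s <= universe:
            raise ValueError(f"gene set {name!r} is not a subset of the universe")
    N = len(universe)
    K = len(set_b)
    n = len(set_a)
    k = len(set_a & set_b)
    table = pd.DataFrame(
        [[k, n - k], [K - k, N - K - n + k]],
        index=[f"{name_a}", f"not_{name_a}"],
        columns=[f"{name_b}", f"not_{name_b}"])
    p_overlap = fisher_ease(k, K, n, N, mode="enrichment")
    p_exclusion = fisher_ease(k, K, n, N, mode="depletion")
    p_two = fisher_ease(k, K, n, N, mode="two-tailed")
    if p_overlap < alpha:
        label = "significant overlap"
    elif p_exclusion < alpha:
        label = "significant exclusion"
    else:
        label = "neither"
    return {"table": table, "k": k, "K": K, "n": n, "N": N,
            "p_overlap": p_overlap, "p_exclusion": p_exclusion,
            "p_two_tailed": p_two, "label": label}
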