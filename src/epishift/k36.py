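"""H3K36me3 redistribution statistics and the EASE-modified Fisher test.

The gene-level H3K36me3 signal is the peak-covered fraction of the gene
span when only peak intervals are available, or the bp-weighted mean
coverage when a binned coverage track is given.  Differential genes are
called at a fold-change threshold on ``log2((s_pert + c)/(s_ref + c))``
with pseudocount ``c``.

Significance of set overlaps uses the Fisher exact test with a modified
EASE score: the overlap count k is decremented by one (floored at zero)
before the test, a conservative variant that damps significance driven
by a single overlapping element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotate import FEATURES
from .intervals import PeakSet

__all__ = [
    "genome_coverage_fraction",
    "peak_feature_stats",
    "gene_k36_signal",
    "differential_k36_genes",
    "differential_k36_regions",
    "cpg_k36_quadrants",
    "fisher_ease",
    "QuadrantTable",
]


# ---------------------------------------------------------------------
# coverage and peak descriptives
# ---------------------------------------------------------------------

def genome_coverage_fraction(peaks: PeakSet, genome_size: int) -> float:
    """Merged peak bp divided by genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return peaks.total_bp() / genome_size


def peak_feature_stats(peaks: PeakSet, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-feature peak counts and length summaries.

    Each merged peak is assigned the feature containing its midpoint
    (a peak can span features; the midpoint rule is the documented
    tie-break).  Returns count, mean length and length quartiles per
    feature.
    """
    merged = peaks.merge()
    if len(merged) == 0:
        return pd.DataFrame(
            0, index=pd.Index(FEATURES, name="feature"),
            columns=["count", "mean_len", "q25", "median_len", "q75"],
        ).astype(float).assign(count=0)
    df = merged.df
    mid = (df["Start"] + df["End"]) // 2
    from .genes import feature_peaksets
    windows = feature_peaksets(genes)
    feature = np.full(len(df), "intergenic", dtype=object)
    for feat in ("body", "terminus", "promoter"):  # reverse precedence
        inside = windows[feat].contains_points(df["Chromosome"], mid)
        feature[inside] = feat
    lengths = (df["End"] - df["Start"]).to_numpy()
    out = []
    for feat in FEATURES:
        ls = lengths[feature == feat]
        out.append({
            "feature": feat, "count": len(ls),
            "mean_len": float(np.mean(ls)) if len(ls) else np.nan,
            "q25": float(np.percentile(ls, 25)) if len(ls) else np.nan,
            "median_len": float(np.median(ls)) if len(ls) else np.nan,
            "q75": float(np.percentile(ls, 75)) if len(ls) else np.nan,
        })
    return pd.DataFrame(out).set_index("feature")


# ---------------------------------------------------------------------
# per-gene signal and differential calls
# ---------------------------------------------------------------------

def gene_k36_signal(genes: pd.DataFrame, peaks_ref: PeakSet,
                    peaks_pert: PeakSet) -> pd.DataFrame:
    """Peak-covered fraction of each gene span under both conditions."""
    chroms = genes["chrom"].to_numpy()
    starts = genes["start"].to_numpy(np.int64)
    ends = genes["end"].to_numpy(np.int64)
    glen = (ends - starts).astype(float)
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "signal_ref": peaks_ref.covered_bp(chroms, starts, ends) / glen,
        "signal_pert": peaks_pert.covered_bp(chroms, starts, ends) / glen,
    })


def differential_k36_genes(signals: pd.DataFrame, fc_threshold: float = 2.0,
                           pseudocount: float = 0.01):
    """Genes gaining / losing the mark at >= fc_threshold fold change.

    ``log2fc = log2((signal_pert + c) / (signal_ref + c))``; gain means
    log2fc >= log2(fc_threshold), loss the mirror image.  Returns
    ``(gain_ids, loss_ids, table_with_log2fc)``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (signals[["signal_ref", "signal_pert"]] < 0).to_numpy().any():
        raise ValueError("signals must be non-negative")
    tab = signals.copy()
    c = pseudocount
    tab["log2fc"] = np.log2((tab["signal_pert"] + c) / (tab["signal_ref"] + c))
    cut = np.log2(fc_threshold)
    gain = list(tab.loc[tab["log2fc"] >= cut, "gene_id"])
    loss = list(tab.loc[tab["log2fc"] <= -cut, "gene_id"])
    return gain, loss, tab


def differential_k36_regions(coverage_ref: pd.DataFrame,
                             coverage_pert: pd.DataFrame,
                             fc_threshold: float = 2.0,
                             pseudocount: float = 1.0):
    """Gain/loss regions from equally binned coverage of two conditions.

    Both inputs need columns ``chrom, start, end, value`` with identical
    binning.  Windows beyond +/- log2(fc_threshold) are merged into
    maximal regions (book-ended flagged windows join).  Returns
    ``(gain PeakSet, loss PeakSet)``.
    """
    key = ["chrom", "start", "end"]
    if len(coverage_ref) != len(coverage_pert) or \
            not coverage_ref[key].reset_index(drop=True).equals(
                coverage_pert[key].reset_index(drop=True)):
        raise ValueError("coverage tracks must share identical bins")
    c = pseudocount
    ratio = np.log2((coverage_pert["value"].to_numpy() + c)
                    / (coverage_ref["value"].to_numpy() + c))
    cut = np.log2(fc_threshold)
    sets = []
    for flag in (ratio >= cut, ratio <= -cut):
        sub = coverage_ref.loc[flag, key]
        ps = PeakSet.from_arrays(sub["chrom"].to_numpy(),
                                 sub["start"].to_numpy(),
                                 sub["end"].to_numpy()) \
            if flag.any() else PeakSet()
        sets.append(ps.merge())
    return tuple(sets)


# ---------------------------------------------------------------------
# CpG x K36 quadrants
# ---------------------------------------------------------------------

@dataclass
class QuadrantTable:
    """Differential-CpG counts in the four (5mC x K36) quadrants."""

    counts: pd.DataFrame      # index hyper/hypo, columns gain/loss
    p_overlap: pd.DataFrame   # one-tailed EASE enrichment p per cell
    p_exclusion: pd.DataFrame  # one-tailed depletion p per cell
    labels: pd.DataFrame      # significant overlap / exclusion / neither
    n_background: int         # manifest probes inside gain|loss regions


def cpg_k36_quadrants(diff_set, gain_regions: PeakSet, loss_regions: PeakSet,
                      manifest: pd.DataFrame, alpha: float = 1e-3) -> QuadrantTable:
    """Assign differential CpGs to (direction x region-type) quadrants.

    The significance background is every manifest probe inside the union
    of gain and loss regions: for the (hyper, gain) cell, k = hyper CpGs
    in gain regions, K = background probes in gain regions, n = hyper
    CpGs in any region, N = background probes in any region; overlap is
    the EASE-modified enrichment p, exclusion the plain depletion p.
    """
    man = manifest.set_index("probe_id")
    in_gain = pd.Series(
        gain_regions.contains_points(man["chrom"], man["pos"])
        if len(gain_regions) else np.zeros(len(man), bool), index=man.index)
    in_loss = pd.Series(
        loss_regions.contains_points(man["chrom"], man["pos"])
        if len(loss_regions) else np.zeros(len(man), bool), index=man.index)
    in_any = in_gain | in_loss
    N = int(in_any.sum())
    counts = pd.DataFrame(0, index=["hyper", "hypo"], columns=["gain", "loss"])
    p_over = counts.astype(float) * np.nan
    p_excl = p_over.copy()
    labels = counts.astype(object).copy()
    for direction in ("hyper", "hypo"):
        probes = pd.Index(getattr(diff_set, direction)).intersection(man.index)
        n_dir = int(in_any.loc[probes].sum())
        for region, mask in (("gain", in_gain), ("loss", in_loss)):
            k = int(mask.loc[probes].sum())
            K = int(mask.sum())
            counts.loc[direction, region] = k
            if N == 0 or K == 0 or n_dir == 0:
                labels.loc[direction, region] = "neither"
                continue
            p_over.loc[direction, region] = fisher_ease(
                k, K, n_dir, N, mode="enrichment")
            p_excl.loc[direction, region] = fisher_ease(
                k, K, n_dir, N, mode="depletion")
            if p_over.loc[direction, region] < alpha:
                labels.loc[direction, region] = "significant overlap"
            elif p_excl.loc[direction, region] < alpha:
                labels.loc[direction, region] = "significant exclusion"
            else:
                labels.loc[direction, region] = "neither"
    return QuadrantTable(counts=counts, p_overlap=p_over, p_exclusion=p_excl,
                         labels=labels, n_background=N)


# ---------------------------------------------------------------------
# Fisher exact with modified EASE score
# ---------------------------------------------------------------------

def fisher_ease(k: int, K: int, n: int, N: int,
                mode: str = "two-tailed") -> float:
    """Fisher exact p for a 2x2 overlap table with the EASE modification.

    The table is (k, K-k; n-k, N-K-n+k): k elements of an n-set overlap a
    K-set inside a universe of N.  For added stringency the overlap is
    replaced by k' = max(k - 1, 0) before the test (the EASE score).

    ``mode``: ``enrichment`` = one-tailed P(X >= k'); ``two-tailed`` =
    sum of hypergeometric point masses <= pmf(k') (the standard
    two-sided Fisher convention); ``depletion`` = one-tailed P(X <= k),
    without the EASE decrement (decrementing would anti-conservatively
    inflate depletion significance).
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"inconsistent margins: k={k}, K={K}, n={n}, N={N}")
    if mode == "depletion":
        return float(min(hypergeom.cdf(k, N, K, n), 1.0))
    kp = max(k - 1, 0)
    lo = max(0, n + K - N)
    hi = min(K, n)
    if mode == "enrichment":
        if kp <= lo:
            return 1.0
        return float(min(hypergeom.sf(kp - 1, N, K, n), 1.0))
    if mode == "two-tailed":
        if kp < lo:  # decremented table would have a negative cell
            return 1.0
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, N, K, n)
        p_obs = hypergeom.pmf(kp, N, K, n)
        # relative tolerance guards against ties broken by rounding
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
        return min(p, 1.0)
    raise ValueError(f"unknown mode: {mode!r}")
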