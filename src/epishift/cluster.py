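"""Variance-ranked CpG selection, two-cluster dendrograms, genotype
segregation and the cross-cohort conserved hypermethylation signature.

Unsupervised hierarchical clustering of the most variable CpGs is the
standard way 450K cohorts are screened for a methylator phenotype: the
dendrogram is cut at the root into two clusters, the clusters are
oriented to the mutation genotype, and segregation is quantified as the
percent of samples in their genotype-concordant cluster with a 2x2
chi-square test (Yates continuity correction, 1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency

__all__ = [
    "top_variable_cpgs",
    "two_cluster",
    "genotype_segregation",
    "conserved_hyper_signature",
    "ClusterResult",
    "SignatureSet",
]

DEFAULT_TOP_N = 10_000
DEFAULT_N_SIG = 200


@dataclass
class ClusterResult:
    probes: list[str]
    labels: pd.Series           # cluster id in {1, 2} per sample
    linkage_method: str
    metric: str
    segregation_percent: float | None = None
    chi2_p: float | None = None


@dataclass
class SignatureSet:
    probes: list[str]                 # ordered, most conserved first
    per_cohort_delta: pd.DataFrame    # member probes x cohorts


def top_variable_cpgs(beta: pd.DataFrame, n: int = DEFAULT_TOP_N) -> list[str]:
    """Top-n probes by across-sample variance (descending).

    Ties are broken by probe id (lexicographic) so the selection is
    deterministic.  Probes with any missing value are excluded before
    ranking.
    """
    if n > len(beta):
        raise ValueError(f"n={n} exceeds probe count {len(beta)}")
    complete = beta.dropna(axis=0)
    var = complete.var(axis=1, ddof=1)
    frame = pd.DataFrame({"v": var.to_numpy(),
                          "pid": var.index.astype(str)})
    order = frame.sort_values(["v", "pid"], ascending=[False, True])
    return list(var.index[order.index[:n]])


def two_cluster(beta_subset: pd.DataFrame, metric: str = "euclidean",
                method: str = "average") -> pd.Series:
    """Agglomerative two-cluster solution over samples (columns).

    Probes are rows; samples are clustered on their probe profiles with
    the configured distance and linkage and the dendrogram is cut at the
    root into exactly two clusters.  Deterministic given inputs.
    """
    if beta_subset.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    X = beta_subset.to_numpy().T
    Z = linkage(pdist(X, metric=metric), method=method)
    labels = fcluster(Z, t=2, criterion="maxclust")
    return pd.Series(labels, index=beta_subset.columns, name="cluster")


def genotype_segregation(labels: pd.Series, genotypes: pd.Series):
    """Percent of samples in their genotype-concordant cluster + chi2 p.

    The two clusters are oriented to the genotype so concordance is
    always >= 50%.  The test is the 2x2 chi-square with Yates continuity
    correction on the cluster x genotype table.
    """
    genotypes = genotypes.reindex(labels.index)
    gvals = sorted(genotypes.dropna().unique())
    cvals = sorted(labels.unique())
    if len(gvals) != 2:
        raise ValueError(f"need exactly 2 genotype groups, got {gvals}")
    if len(cvals) != 2:
        raise ValueError(f"need exactly 2 clusters, got {cvals}")
    tab = pd.crosstab(labels, genotypes)
    concordant = max(
        tab.loc[cvals[0], gvals[0]] + tab.loc[cvals[1], gvals[1]],
        tab.loc[cvals[0], gvals[1]] + tab.loc[cvals[1], gvals[0]],
    )
    percent = 100.0 * concordant / len(labels)
    chi2 = chi2_contingency(tab.to_numpy(), correction=True)
    return percent, float(chi2.pvalue)


def conserved_hyper_signature(cohort_tracks: dict[str, pd.DataFrame],
                              n_sig: int = DEFAULT_N_SIG,
                              threshold: float = 0.0) -> SignatureSet:
    """The most conserved hypermethylated CpGs across cohorts.

    Candidates are probes hypermethylated (delta >= threshold, strictly
    positive when threshold is 0) in every cohort; they are ranked by the
    minimum delta across cohorts, descending — the probes whose weakest
    cohort is still strongest — with probe-id tie-break.  If fewer than
    ``n_sig`` candidates exist, all are returned with a warning.
    """
    if len(cohort_tracks) < 2:
        raise ValueError("need >= 2 cohorts for a conserved signature")
    deltas = pd.DataFrame({name: t["delta"]
                           for name, t in cohort_tracks.items()}).dropna()
    floor = threshold if threshold > 0 else np.nextafter(0, 1)
    candidates = deltas[(deltas >= floor).all(axis=1)]
    if len(candidates) < n_sig:
        warnings.warn(
            f"only {len(candidates)} conserved hypermethylated probes; "
            f"requested {n_sig}", stacklevel=2)
    ranked = candidates.assign(
        _min=candidates.min(axis=1),
        _pid=candidates.index.astype(str),
    ).sort_values(["_min", "_pid"], ascending=[False, True])
    chosen = ranked.index[:n_sig]
    return SignatureSet(probes=list(chosen),
                        per_cohort_delta=deltas.loc[chosen])
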