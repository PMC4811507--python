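"""Per-probe differential methylation (delta-beta) and its summaries.

Delta-beta is the unit of differential methylation throughout:
``delta = mean(beta, perturbed samples) - mean(beta, reference samples)``
per probe.  Differential CpGs are called by a closed threshold rule
``|delta| >= t`` (t = 0.2 for isogenic cell-line comparisons, 0.1 for
tumor-cohort comparisons), not by a per-probe hypothesis test — the rule
is deterministic and symmetric in direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import FEATURES

__all__ = [
    "compute_delta_beta",
    "classify_diff_cpgs",
    "hyper_fraction",
    "feature_enrichment",
    "metagene_profile",
    "percent_change_total_5mC",
    "rank_sum_pvalues",
    "DiffCpGSet",
]

CELLLINE_THRESHOLD = 0.2
COHORT_THRESHOLD = 0.1


@dataclass
class DiffCpGSet:
    """Hyper-/hypomethylated probe sets at one |delta| threshold."""

    threshold: float
    hyper: list[str] = field(default_factory=list)
    hypo: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.hyper) & set(self.hypo)
        if overlap:
            raise ValueError(f"probe in both classes: {sorted(overlap)[0]}")

    @property
    def n_total(self) -> int:
        return len(self.hyper) + len(self.hypo)


def compute_delta_beta(beta: pd.DataFrame, sheet: pd.DataFrame,
                       grouping: str = "condition") -> pd.DataFrame:
    """Per-probe group-mean difference, perturbed minus reference.

    ``grouping`` names the sample-sheet column defining the two groups:
    ``condition`` (reference/perturbed, cell-line mode) or ``genotype``
    (WT/MUT, cohort mode).  Missing values are excluded per probe and per
    group; a probe with no usable value in either group is dropped.
    Groups may be singletons (one KO clone vs one parental sample).

    Returns a DataFrame indexed by probe_id with columns
    ``delta, n_ref, n_pert``.
    """
    labels = {"condition": ("reference", "perturbed"),
              "genotype": ("WT", "MUT")}
    if grouping not in labels:
        raise ValueError(f"unknown grouping column: {grouping!r}")
    ref_lab, pert_lab = labels[grouping]
    sheet = sheet.loc[sheet["sample_id"].isin(beta.columns)] \
        if "sample_id" in sheet.columns else sheet.loc[sheet.index.isin(beta.columns)]
    ref_cols = sheet.index[sheet[grouping] == ref_lab]
    pert_cols = sheet.index[sheet[grouping] == pert_lab]
    if len(ref_cols) == 0 or len(pert_cols) == 0:
        raise ValueError(
            f"need >=1 sample in each {grouping} group "
            f"(got {len(ref_cols)} {ref_lab}, {len(pert_cols)} {pert_lab})")
    ref = beta[list(ref_cols)]
    pert = beta[list(pert_cols)]
    n_ref = ref.notna().sum(axis=1)
    n_pert = pert.notna().sum(axis=1)
    track = pd.DataFrame({
        "delta": pert.mean(axis=1) - ref.mean(axis=1),
        "n_ref": n_ref, "n_pert": n_pert,
    })
    keep = (n_ref > 0) & (n_pert > 0)
    return track.loc[keep]


def classify_diff_cpgs(track: pd.DataFrame, threshold: float) -> DiffCpGSet:
    """Partition probes with |delta| >= threshold by sign (closed rule)."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1]: {threshold}")
    delta = track["delta"]
    hyper = list(track.index[delta >= threshold])
    hypo = list(track.index[delta <= -threshold])
    return DiffCpGSet(threshold=threshold, hyper=hyper, hypo=hypo)


def hyper_fraction(diff_set: DiffCpGSet) -> float:
    """|hyper| / (|hyper| + |hypo|)."""
    if diff_set.n_total == 0:
        raise ValueError("no differential CpGs: hyper fraction undefined")
    return len(diff_set.hyper) / diff_set.n_total


def feature_enrichment(diff_set: DiffCpGSet, manifest: pd.DataFrame) -> pd.DataFrame:
    """Feature-normalised enrichment of differential CpGs.

    For each genomic feature and each direction: the fraction of
    differential CpGs falling in the feature divided by the fraction of
    all manifest probes in it (the array background).  A feature with no
    background probes gets NaN ratios.
    """
    man = manifest.set_index("probe_id")
    missing = [p for p in diff_set.hyper + diff_set.hypo if p not in man.index]
    if missing:
        raise ValueError(f"probe not in manifest: {missing[0]!r}")
    bg_counts = man["feature"].value_counts().reindex(FEATURES, fill_value=0)
    bg_frac = bg_counts / bg_counts.sum()
    rows = {}
    for direction in ("hyper", "hypo"):
        probes = getattr(diff_set, direction)
        counts = (man.loc[probes, "feature"].value_counts()
                  .reindex(FEATURES, fill_value=0))
        frac = counts / counts.sum() if counts.sum() else counts * np.nan
        rows[f"{direction}_count"] = counts
        rows[f"{direction}_fraction"] = frac
        rows[f"{direction}_ratio"] = (frac / bg_frac).where(bg_counts > 0)
    out = pd.DataFrame(rows)
    out.insert(0, "background_fraction", bg_frac)
    out.index.name = "feature"
    return out


def metagene_profile(values: pd.Series, manifest: pd.DataFrame,
                     genes: pd.DataFrame, n_bins: int = 100,
                     flank_frac: float = 0.25,
                     gene_ids=None) -> pd.DataFrame:
    """Strand-oriented binned profile across gene bodies with flanks.

    Each probe inside a gene (or its proportional flanks) is mapped to a
    fractional coordinate x in [-flank_frac, 1 + flank_frac] with x = 0
    at the TSS and x = 1 at the TES, regardless of strand.  Probe values
    are averaged per gene per bin, then bins are averaged across genes,
    so long genes do not dominate.

    Returns a DataFrame with ``bin_mid`` (fractional coordinate),
    ``mean`` and ``n_genes`` per bin; also reports ``n_genes_skipped``
    (genes without probes) in ``DataFrame.attrs``.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    use = genes if gene_ids is None else genes.loc[list(gene_ids)]
    edges = np.linspace(-flank_frac, 1 + flank_frac, n_bins + 1)
    sums = np.zeros(n_bins)
    gene_counts = np.zeros(n_bins, dtype=int)
    skipped = 0
    man = manifest.set_index("probe_id")
    vals = values.dropna()
    man = man.loc[man.index.intersection(vals.index)]
    for _, g in use.iterrows():
        length = g.end - g.start
        lo = g.start - flank_frac * length
        hi = g.end + flank_frac * length
        sel = man[(man["chrom"] == g.chrom) & (man["pos"] >= lo)
                  & (man["pos"] < hi)]
        if len(sel) == 0:
            skipped += 1
            continue
        if g.strand == "+":
            x = (sel["pos"].to_numpy() - g.start) / length
        else:
            x = (g.end - 1 - sel["pos"].to_numpy()) / length
        b = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        v = vals.loc[sel.index].to_numpy()
        per_bin = pd.Series(v).groupby(b).mean()
        sums[per_bin.index] += per_bin.to_numpy()
        gene_counts[per_bin.index] += 1
    mean = np.divide(sums, gene_counts, out=np.full(n_bins, np.nan),
                     where=gene_counts > 0)
    out = pd.DataFrame({
        "bin_mid": (edges[:-1] + edges[1:]) / 2,
        "mean": mean,
        "n_genes": gene_counts,
    })
    out.attrs["n_genes_skipped"] = skipped
    return out


def percent_change_total_5mC(reference_value: float,
                             perturbed_value: float) -> float:
    """Percent change of a global 5mC measurement (e.g. 5mC per 10^6 dC).

    ``100 * (perturbed - reference) / reference``; the reference must be
    positive.
    """
    if reference_value <= 0:
        raise ValueError("reference 5mC value must be positive")
    return 100.0 * (perturbed_value - reference_value) / reference_value


def rank_sum_pvalues(beta: pd.DataFrame, sheet: pd.DataFrame,
                     grouping: str = "genotype") -> pd.Series:
    """Two-sided rank-sum p per probe (volcano plots; exploratory only)."""
    labels = {"condition": ("reference", "perturbed"),
              "genotype": ("WT", "MUT")}
    ref_lab, pert_lab = labels[grouping]
    ref = beta[sheet.index[sheet[grouping] == ref_lab]].to_numpy()
    pert = beta[sheet.index[sheet[grouping] == pert_lab]].to_numpy()
    stat = sps.mannwhitneyu(pert, ref, axis=1, alternative="two-sided",
                            nan_policy="omit")
    return pd.Series(stat.pvalue, index=beta.index, name="p_ranksum")
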