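"""Synthetic methylome / H3K36me3 / expression cohorts with known truth.

The generator emulates the data structure of a SETD2 loss-of-function
study: a small genome of stranded genes with intergenic space; CpG
probes placed with exponential spacing; baseline beta values that are
low at promoters and poised enhancers, high over bodies of expressed
genes and intermediate in intergenic space; and a perturbed ("KO/mutant")
condition carrying

* planted hypermethylation blocks — runs of consecutive probes at
  intergenic / low-expressed-gene / H3K4me1-only loci shifted up by
  ``planted_delta``,
* hypomethylation at the 3'-termini of high-expressed genes that lose
  gene-body H3K36me3,
* ectopic H3K36me3 peaks over a configured fraction of the planted
  blocks, and
* >=2-fold expression up-shifts of low-expressed genes inside planted
  blocks that acquired ectopic H3K36me3.

Per-sample measurement noise is Beta(mu*kappa, (1-mu)*kappa) around the
true mean mu, with kappa = ``noise_concentration``; the bounded support
is the only clipping applied.  Everything is deterministic under a fixed
seed, and a :class:`SyntheticTruth` records every planted effect so that
downstream recovery can be scored from emitted files alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .annotate import annotate_probes
from .genes import build_gene_table
from .intervals import PeakSet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_genome",
    "generate_k36_profiles",
    "generate_beta_cohort",
    "generate_expression",
    "simulate_study",
]


class ConfigError(ValueError):
    """Invalid or infeasible synthetic configuration."""


# baseline (reference-condition) mean beta by context
BASELINE_BETA = {
    "promoter": 0.10,
    "poised_enhancer": 0.15,   # H3K4me1-only probes
    "active_enhancer": 0.05,   # H3K27ac-marked probes
    "body_high": 0.80,
    "terminus_high": 0.80,
    "body_low": 0.50,
    "terminus_low": 0.50,
    "intergenic": 0.50,
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are desk-test (cell-line) sized."""

    n_chroms: int = 2
    chrom_len: int = 5_000_000
    n_genes: int = 200
    probe_spacing: int = 500          # mean bp between probes
    frac_high_expr: float = 0.5
    n_reference_samples: int = 3
    n_perturbed_samples: int = 3
    planted_block_count: int = 50
    planted_block_len: int = 25       # probes per block (~12 kb domains)
    planted_delta: float = 0.25
    terminus_hypo_delta: float = 0.20
    n_terminus_hypo_genes: int = 30
    noise_concentration: float = 100.0
    ectopic_gain_frac: float = 0.6
    k4me1_target_frac: float = 0.5    # of low-expressed genes
    frac_k36_loss: float = 0.6        # of high-expressed genes losing body K36
    gene_len_range: tuple[int, int] = (5_000, 40_000)
    gap_range: tuple[int, int] = (10_000, 45_000)
    low_zero_frac: float = 0.3        # low-tier genes with RPKM exactly 0
    expression_upshift: float = 4.0
    seed: int = 0

    @classmethod
    def cellline(cls, seed: int = 0, **kw) -> "SyntheticConfig":
        """Cell-line study conditions: 3 samples/arm, planted delta 0.25."""
        return cls(seed=seed, **kw)

    @classmethod
    def cohort(cls, seed: int = 0, **kw) -> "SyntheticConfig":
        """Tumor-cohort conditions: 20 samples/arm, planted delta 0.15 on
        ~5% of probes (40 blocks x 25 probes of ~20,000), kappa = 60."""
        defaults = dict(
            n_reference_samples=20, n_perturbed_samples=20,
            planted_block_count=40, planted_block_len=25,
            planted_delta=0.15, terminus_hypo_delta=0.12,
            noise_concentration=60.0,
        )
        defaults.update(kw)
        return cls(seed=seed, **defaults)

    def validate(self) -> None:
        if min(self.n_chroms, self.chrom_len, self.n_genes + 1,
               self.probe_spacing, self.planted_block_count + 1,
               self.planted_block_len) <= 0:
            raise ConfigError("counts and sizes must be positive")
        for name in ("planted_delta", "terminus_hypo_delta"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must be in (0, 1): {v}")
        if not (0 <= self.frac_high_expr <= 1):
            raise ConfigError("frac_high_expr must be in [0, 1]")
        if self.noise_concentration <= 0:
            raise ConfigError("noise_concentration must be positive")
        # planted shifts must keep every reachable mean inside (0, 1)
        hi = max(BASELINE_BETA["intergenic"], BASELINE_BETA["body_low"],
                 BASELINE_BETA["poised_enhancer"], BASELINE_BETA["promoter"])
        if hi + self.planted_delta >= 1:
            raise ConfigError(
                f"planted_delta {self.planted_delta} pushes mean beta to "
                f"{hi + self.planted_delta} >= 1")
        if BASELINE_BETA["terminus_high"] - self.terminus_hypo_delta <= 0:
            raise ConfigError("terminus_hypo_delta pushes mean beta <= 0")


@dataclass
class SyntheticTruth:
    """Planted-effect record for parameter-recovery scoring."""

    planted_blocks: list[dict] = field(default_factory=list)
    ectopic_k36_regions: list[dict] = field(default_factory=list)
    lost_k36_genes: list[str] = field(default_factory=list)
    terminus_hypo_genes: list[str] = field(default_factory=list)
    upregulated_genes: list[str] = field(default_factory=list)
    mu_ref: "pd.Series | None" = None   # per-probe true mean, reference
    mu_pert: "pd.Series | None" = None  # per-probe true mean, perturbed

    @property
    def planted_probe_ids(self) -> list[str]:
        return [p for b in self.planted_blocks for p in b["probe_ids"]]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["mu_ref"] = None if self.mu_ref is None else self.mu_ref.to_dict()
        d["mu_pert"] = None if self.mu_pert is None else self.mu_pert.to_dict()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        for key in ("mu_ref", "mu_pert"):
            if d.get(key) is not None:
                d[key] = pd.Series(d[key])
        return cls(**d)


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulated study emits."""

    config: SyntheticConfig
    genes: pd.DataFrame
    manifest: pd.DataFrame
    k4me1: PeakSet
    k27ac: PeakSet
    truth: SyntheticTruth
    k36_ref: PeakSet
    k36_pert: PeakSet
    k36_signal: pd.DataFrame
    beta: pd.DataFrame
    sheet: pd.DataFrame
    expression: pd.DataFrame

    @property
    def genome_size(self) -> int:
        return self.config.n_chroms * self.config.chrom_len

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "genes": "genes.tsv", "manifest": "manifest.tsv",
            "k4me1": "k4me1.bed", "k27ac": "k27ac.bed",
            "k36_ref": "k36_reference.bed", "k36_pert": "k36_perturbed.bed",
            "k36_signal": "k36_gene_signal.tsv", "beta": "beta.tsv",
            "sheet": "samples.csv", "expression": "expression.tsv",
            "truth": "truth.json"}.items()}
        eio.write_gene_models(self.genes, paths["genes"])
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        self.k4me1.write_bed(paths["k4me1"])
        self.k27ac.write_bed(paths["k27ac"])
        self.k36_ref.write_bed(paths["k36_ref"])
        self.k36_pert.write_bed(paths["k36_pert"])
        self.k36_signal.to_csv(paths["k36_signal"], sep="\t", index=False)
        eio.write_beta_matrix(self.beta, paths["beta"])
        eio.write_sample_sheet(self.sheet, paths["sheet"])
        eio.write_expression(self.expression, paths["expression"])
        self.truth.to_json(paths["truth"])
        return paths


def _rngs(config: SyntheticConfig) -> dict[str, np.random.Generator]:
    """Independent child streams per stage, all derived from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    names = ("genome", "probes", "effects", "k36", "beta", "expression")
    return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


# ---------------------------------------------------------------------
# genome, marks, probes
# ---------------------------------------------------------------------

def generate_genome(config: SyntheticConfig):
    """Tile genes with intergenic gaps, place probes, set enhancer marks.

    Returns ``(genes, manifest, {"k4me1": PeakSet, "k27ac": PeakSet})``.
    The manifest carries feature and enhancer-class labels produced by the
    package's own annotator, so synthetic data and real data share one
    annotation path.
    """
    config.validate()
    rng = _rngs(config)["genome"]
    prng = _rngs(config)["probes"]

    # --- genes ---
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    rows = []
    gid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        k = per_chrom[ci]
        glens = rng.integers(*config.gene_len_range, size=k) if k else np.array([], int)
        gaps = rng.integers(*config.gap_range, size=k + 1).astype(float)
        genic = int(glens.sum())
        # rescale the drawn gaps so the tiling always fits the chromosome
        budget = config.chrom_len - genic
        if budget <= k:  # needs >=1 bp per gap
            raise ConfigError(
                f"genome too small: could not fit {k} genes "
                f"on {chrom} of {config.chrom_len} bp")
        gaps = np.maximum((gaps * min(1.0, budget / gaps.sum())).astype(int), 1)
        cursor = 0
        for gi in range(k):
            start = cursor + int(gaps[gi])
            end = start + int(glens[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid:04d}", chrom, start, end, strand))
            gid += 1
            cursor = end
    gene_df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    # --- expression tiers (a genome property: which genes are expressed) ---
    n_high = int(round(config.frac_high_expr * len(gene_df)))
    high_idx = rng.choice(len(gene_df), size=n_high, replace=False)
    tier = np.full(len(gene_df), "low", dtype=object)
    tier[high_idx] = "high"
    gene_df["tier"] = tier

    genes = build_gene_table(gene_df)

    # --- enhancer marks (normal-tissue-style annotation) ---
    # enhancers are distal: a ~2 kb element 4-9 kb upstream of the TSS.
    # active genes carry K27ac (half also K4me1); a fraction of silent
    # developmental-style genes carry K4me1 alone = poised
    k4_rows, k27_rows = [], []
    for _, g in genes.iterrows():
        dist = int(rng.integers(4_000, 9_000))
        if g.strand == "+":
            hi = max(int(g.tss) - dist, 0)
            lo = max(hi - 2_000, 0)
        else:
            lo = min(int(g.tss) + dist, config.chrom_len)
            hi = min(lo + 2_000, config.chrom_len)
        if hi <= lo:
            continue
        if g.tier == "high":
            k27_rows.append((g.chrom, lo, hi))
            if rng.random() < 0.5:
                k4_rows.append((g.chrom, lo, hi))
        else:
            if rng.random() < config.k4me1_target_frac:
                k4_rows.append((g.chrom, lo, hi))
    k4me1 = PeakSet(pd.DataFrame(k4_rows, columns=["Chromosome", "Start", "End"])
                    if k4_rows else None).merge()
    k27ac = PeakSet(pd.DataFrame(k27_rows, columns=["Chromosome", "Start", "End"])
                    if k27_rows else None).merge()

    # --- probes: exponential spacing, denser at promoters (450K-style,
    # where promoter/CGI probes are heavily over-represented) ---
    probe_rows = []
    pid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        gaps = prng.exponential(config.probe_spacing,
                                size=int(2.5 * config.chrom_len / config.probe_spacing))
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos < config.chrom_len]
        extra = []
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            width = g.prom_end - g.prom_start
            e = g.prom_start + np.cumsum(prng.exponential(
                config.probe_spacing / 3.0,
                size=int(6 * width / config.probe_spacing))).astype(np.int64)
            extra.append(e[(e < g.prom_end) & (e < config.chrom_len)])
        if extra:
            pos = np.concatenate([pos] + extra)
        pos = np.unique(pos)
        for p in pos:
            probe_rows.append((f"cg{pid:07d}", chrom, int(p)))
            pid += 1
    positions = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
    manifest = annotate_probes(positions, genes, k4me1, k27ac)
    return genes, manifest, {"k4me1": k4me1, "k27ac": k27ac}


def _baseline_means(manifest: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    tier = genes["tier"] if "tier" in genes.columns else pd.Series(dtype=object)
    gene_tier = manifest["nearest_gene"].map(tier).fillna("low")
    mu = np.full(len(manifest), BASELINE_BETA["intergenic"])
    feat = manifest["feature"].to_numpy()
    mu[feat == "promoter"] = BASELINE_BETA["promoter"]
    for f in ("body", "terminus"):
        for t in ("high", "low"):
            sel = (feat == f) & (gene_tier == t).to_numpy()
            mu[sel] = BASELINE_BETA[f"{f}_{t}"]
    enh = manifest["enhancer_class"].to_numpy()
    mu[enh == "k4me1_only"] = BASELINE_BETA["poised_enhancer"]
    mu[(enh == "k4me1_k27ac") | (enh == "k27ac_only")] = \
        BASELINE_BETA["active_enhancer"]
    return mu


def plant_effects(genes: pd.DataFrame, manifest: pd.DataFrame,
                  config: SyntheticConfig) -> SyntheticTruth:
    """Choose planted blocks and terminus-hypo genes; build true means."""
    rng = _rngs(config)["effects"]
    man = manifest.reset_index(drop=True)
    mu_ref = _baseline_means(man, genes)

    tier = genes["tier"] if "tier" in genes.columns else pd.Series(dtype=object)
    gene_tier = man["nearest_gene"].map(tier).fillna("low").to_numpy()

    # genes losing gene-body H3K36me3 (subset of expressed genes)
    high_genes = list(genes.index[genes.get("tier", "low") == "high"])
    n_loss = int(round(config.frac_k36_loss * len(high_genes)))
    lost = sorted(rng.choice(high_genes, size=n_loss, replace=False)) \
        if n_loss else []
    n_th = min(config.n_terminus_hypo_genes, len(lost))
    term_hypo = sorted(rng.choice(lost, size=n_th, replace=False)) if n_th else []

    # eligibility for hypermethylation blocks: intergenic space or loci of
    # silent genes (incl. their poised promoters); never expressed genes
    eligible = (man["feature"] == "intergenic").to_numpy() | (gene_tier == "low")
    eligible &= ~man["enhancer_class"].isin(["k4me1_k27ac", "k27ac_only"]).to_numpy()

    # candidate runs of consecutive eligible probes on one chromosome
    L = config.planted_block_len
    chrom_codes = man["chrom"].to_numpy()
    starts = []
    run_start = None
    for i in range(len(man) + 1):
        ok = (i < len(man) and eligible[i]
              and (run_start is None or chrom_codes[i] == chrom_codes[run_start]))
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            for s in range(run_start, i - L + 1):
                starts.append(s)
            run_start = None
            if i < len(man) and eligible[i]:
                run_start = i
    truth = SyntheticTruth(lost_k36_genes=[str(g) for g in lost],
                           terminus_hypo_genes=[str(g) for g in term_hypo])
    # poised (H3K4me1-only) loci are preferred hypermethylation targets:
    # roughly half the blocks are drawn from runs containing poised probes
    poised = (man["enhancer_class"] == "k4me1_only").to_numpy()
    has_poised = np.array([poised[s:s + L].any() for s in starts]) \
        if starts else np.array([], bool)
    chosen: list[int] = []
    taken = np.zeros(len(man), dtype=bool)
    order = rng.permutation(len(starts))
    n_poised_target = config.planted_block_count // 2

    def _try(s: int) -> bool:
        lo, hi = max(s - 1, 0), min(s + L + 1, len(man))
        if taken[lo:hi].any():   # keep blocks disjoint and non-adjacent
            return False
        chosen.append(s)
        taken[s:s + L] = True
        return True

    for i in order:
        if len(chosen) >= n_poised_target:
            break
        if has_poised[i]:
            _try(starts[i])
    for i in order:
        if len(chosen) == config.planted_block_count:
            break
        _try(starts[i])
    if len(chosen) < config.planted_block_count:
        raise ConfigError(
            f"only {len(chosen)} of {config.planted_block_count} planted "
            "blocks fit the genome; reduce block count/length")

    mu_pert = mu_ref.copy()
    for s in sorted(chosen):
        block = man.iloc[s:s + L]
        mu_pert[s:s + L] = mu_ref[s:s + L] + config.planted_delta
        truth.planted_blocks.append({
            "chrom": str(block["chrom"].iloc[0]),
            "start": int(block["pos"].iloc[0]),
            "end": int(block["pos"].iloc[-1]) + 1,
            "probe_ids": [str(p) for p in block["probe_id"]],
        })

    if term_hypo:
        in_hypo = ((man["feature"] == "terminus")
                   & man["nearest_gene"].isin(term_hypo)).to_numpy()
        mu_pert[in_hypo] = mu_ref[in_hypo] - config.terminus_hypo_delta

    if ((mu_pert <= 0) | (mu_pert >= 1)).any() or ((mu_ref <= 0) | (mu_ref >= 1)).any():
        raise ConfigError("planted effects push a true mean outside (0, 1)")

    truth.mu_ref = pd.Series(mu_ref, index=man["probe_id"].to_numpy())
    truth.mu_pert = pd.Series(mu_pert, index=man["probe_id"].to_numpy())
    return truth


# ---------------------------------------------------------------------
# H3K36me3 profiles
# ---------------------------------------------------------------------

def generate_k36_profiles(genes: pd.DataFrame, truth: SyntheticTruth,
                          config: SyntheticConfig):
    """Reference and perturbed H3K36me3 peak sets plus per-gene signals.

    Reference peaks blanket the bodies (through the 3'-terminus) of
    expressed genes.  The perturbed condition drops peaks of
    ``truth.lost_k36_genes`` and adds ectopic intergenic peaks over a
    configured fraction of the planted blocks (recorded in the truth).
    """
    rng = _rngs(config)["k36"]
    ref_rows, pert_rows = [], []
    for gene_id, g in genes.iterrows():
        if g.get("tier", "low") != "high":
            continue
        lo = int(min(g.body_start, g.term_start))
        hi = int(max(g.body_end, g.term_end))
        if hi <= lo:
            lo, hi = int(g.start), int(g.end)
        ref_rows.append((g.chrom, lo, hi))
        if gene_id not in truth.lost_k36_genes:
            pert_rows.append((g.chrom, lo, hi))
    n_ectopic = int(round(config.ectopic_gain_frac * len(truth.planted_blocks)))
    order = rng.permutation(len(truth.planted_blocks))
    truth.ectopic_k36_regions = []
    for bi in sorted(order[:n_ectopic]):
        b = truth.planted_blocks[bi]
        region = {"chrom": b["chrom"], "start": max(b["start"] - 500, 0),
                  "end": b["end"] + 500}
        truth.ectopic_k36_regions.append(region)
        pert_rows.append((region["chrom"], region["start"], region["end"]))
    cols = ["Chromosome", "Start", "End"]
    k36_ref = PeakSet(pd.DataFrame(ref_rows, columns=cols) if ref_rows else None).merge()
    k36_pert = PeakSet(pd.DataFrame(pert_rows, columns=cols) if pert_rows else None).merge()

    # per-gene signal: peak-covered fraction of the gene span
    from .k36 import gene_k36_signal
    sig = gene_k36_signal(genes, k36_ref, k36_pert)
    return k36_ref, k36_pert, sig


# ---------------------------------------------------------------------
# beta cohort and expression
# ---------------------------------------------------------------------

def generate_beta_cohort(manifest: pd.DataFrame, truth: SyntheticTruth,
                         config: SyntheticConfig, cohort: str = "synthetic",
                         noise_seed: int | None = None):
    """Draw per-sample beta values around the true means.

    Returns ``(beta matrix, sample sheet)``; reference samples are
    genotype WT, perturbed samples MUT.  ``noise_seed`` overrides the
    measurement-noise stream so several cohorts can share one genome and
    truth while observing independent samples.
    """
    rng = (_rngs(config)["beta"] if noise_seed is None
           else np.random.default_rng(noise_seed))
    k = config.noise_concentration
    mu_ref = truth.mu_ref.reindex(manifest["probe_id"]).to_numpy()
    mu_pert = truth.mu_pert.reindex(manifest["probe_id"]).to_numpy()
    cols, data, meta = [], [], []
    for i in range(config.n_reference_samples):
        cols.append(f"{cohort}_ref{i + 1}")
        data.append(rng.beta(mu_ref * k, (1 - mu_ref) * k))
        meta.append((cols[-1], "reference", "WT", cohort))
    for i in range(config.n_perturbed_samples):
        cols.append(f"{cohort}_mut{i + 1}")
        data.append(rng.beta(mu_pert * k, (1 - mu_pert) * k))
        meta.append((cols[-1], "perturbed", "MUT", cohort))
    beta = pd.DataFrame(
        np.column_stack(data) if data else np.empty((len(manifest), 0)),
        index=pd.Index(manifest["probe_id"], name="probe_id"), columns=cols)
    sheet = pd.DataFrame(
        meta, columns=["sample_id", "condition", "genotype", "cohort"]
    ).set_index("sample_id", drop=False)
    return beta, sheet


def generate_expression(genes: pd.DataFrame, truth: SyntheticTruth,
                        config: SyntheticConfig, sheet: pd.DataFrame):
    """Per-sample RPKM table; plants >=2-fold up-shifts inside ectopic blocks.

    High-tier genes draw log-normal RPKM around ~20, low-tier around ~0.2
    with a configured fraction of exact zeros.  Silent/low genes inside
    planted blocks overlapping ectopic H3K36me3 get an expression
    up-shift in the perturbed condition, recorded in
    ``truth.upregulated_genes``.
    """
    rng = _rngs(config)["expression"]
    tier = genes.get("tier", pd.Series("low", index=genes.index))
    n = len(genes)
    high = (tier == "high").to_numpy()
    ref_mean = np.where(
        high,
        np.exp(rng.normal(np.log(20.0), 1.0, size=n)),
        np.exp(rng.normal(np.log(0.2), 0.8, size=n)),
    )
    zeros = (~high) & (rng.random(n) < config.low_zero_frac)
    ref_mean[zeros] = 0.0

    # genes inside ectopic-K36 planted blocks: perturbed up-shift
    ect = PeakSet(pd.DataFrame(truth.ectopic_k36_regions)
                  .rename(columns={"chrom": "Chromosome", "start": "Start",
                                   "end": "End"})
                  if truth.ectopic_k36_regions else None)
    spans = PeakSet(pd.DataFrame({
        "Chromosome": genes["chrom"].to_numpy(),
        "Start": genes["start"].to_numpy(),
        "End": genes["end"].to_numpy(),
        "gene_pos": np.arange(n),    # survives PeakSet sorting
    }))
    hit_in_gene_order = np.zeros(n, bool)
    if len(ect):
        hit_in_gene_order[spans.df["gene_pos"].to_numpy()] = \
            spans.overlaps_intervals(ect)
    up = hit_in_gene_order & ~high
    pert_mean = ref_mean.copy()
    pert_mean[up] = np.maximum(ref_mean[up] * config.expression_upshift, 0.05)
    truth.upregulated_genes = [str(g) for g in genes.index[up]]

    cols, data = [], []
    for sample_id, row in sheet.iterrows():
        mean = ref_mean if row["condition"] == "reference" else pert_mean
        noise = np.exp(rng.normal(0.0, 0.2, size=n))
        data.append(np.where(mean > 0, mean * noise, 0.0))
        cols.append(sample_id)
    expr = pd.DataFrame(np.column_stack(data), index=genes.index, columns=cols)
    expr.index.name = "gene_id"
    return expr


def simulate_study(config: SyntheticConfig, cohort: str = "synthetic") -> SyntheticStudy:
    """Run every generator stage under one seed and bundle the outputs."""
    genes, manifest, enh = generate_genome(config)
    truth = plant_effects(genes, manifest, config)
    k36_ref, k36_pert, k36_signal = generate_k36_profiles(genes, truth, config)
    beta, sheet = generate_beta_cohort(manifest, truth, config, cohort=cohort)
    expression = generate_expression(genes, truth, config, sheet)
    return SyntheticStudy(
        config=config, genes=genes, manifest=manifest,
        k4me1=enh["k4me1"], k27ac=enh["k27ac"], truth=truth,
        k36_ref=k36_ref, k36_pert=k36_pert, k36_signal=k36_signal,
        beta=beta, sheet=sheet, expression=expression,
    )
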