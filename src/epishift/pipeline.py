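"""End-to-end workflows: cell-line analysis, cohort analysis, benchmark.

Each workflow reads a study directory in the package's file dialects
(exactly what the simulator emits), runs the analysis stages, writes TSV
tables plus a machine-readable ``summary.json`` into the output
directory, and returns the summary dict.  Every summary carries the seed
and a hash of the configuration so reruns are attributable; inputs are
never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as clu
from . import diffmeth as dm
from . import dmr as dmr_mod
from . import enhancer as enh
from . import io as eio
from . import k36 as k36_mod
from .intervals import PeakSet, read_bed
from .simulate import SyntheticConfig, SyntheticStudy, SyntheticTruth, simulate_study

log = logging.getLogger("epishift")

__all__ = ["PipelineConfig", "StudyData", "load_study",
           "run_cellline_analysis", "run_cohort_analysis",
           "run_synthetic_benchmark"]


@dataclass
class PipelineConfig:
    """All tunable constants of the workflows in one declarative object."""

    mode: str = "synthetic"            # cellline | cohort | synthetic
    indir: str | None = None
    outdir: str = "epishift_out"
    delta_threshold_cellline: float = 0.2
    delta_threshold_cohort: float = 0.1
    dmr_min_run: int = 8
    dmr_delta_min: float = 0.2
    fc_threshold: float = 2.0
    pseudocount: float = 0.01
    k36_pseudocount: float = 0.01
    tier_cutoff_rpkm: float = 1.0
    top_n_variable: int = 10_000
    n_signature: int = 200
    alpha: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        positive = ["delta_threshold_cellline", "delta_threshold_cohort",
                    "dmr_min_run", "dmr_delta_min", "fc_threshold",
                    "pseudocount", "k36_pseudocount", "tier_cutoff_rpkm",
                    "top_n_variable", "n_signature", "alpha"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("cellline", "cohort", "synthetic"):
            raise ValueError(f"unknown mode: {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        """Hash of the analytic constants (paths excluded)."""
        d = {k: v for k, v in asdict(self).items()
             if k not in ("indir", "outdir")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StudyData:
    """In-memory bundle of one study's inputs."""

    genes: pd.DataFrame
    manifest: pd.DataFrame
    beta: pd.DataFrame
    sheet: pd.DataFrame
    expression: pd.DataFrame | None = None
    k4me1: PeakSet = field(default_factory=PeakSet)
    k27ac: PeakSet = field(default_factory=PeakSet)
    k36_ref: PeakSet = field(default_factory=PeakSet)
    k36_pert: PeakSet = field(default_factory=PeakSet)
    genome_size: int | None = None

    @classmethod
    def from_study(cls, study: SyntheticStudy) -> "StudyData":
        return cls(genes=study.genes, manifest=study.manifest,
                   beta=study.beta, sheet=study.sheet,
                   expression=study.expression, k4me1=study.k4me1,
                   k27ac=study.k27ac, k36_ref=study.k36_ref,
                   k36_pert=study.k36_pert, genome_size=study.genome_size)


def load_study(indir) -> StudyData:
    """Read a study directory written by the simulator / upstream tools."""
    indir = Path(indir)
    required = ["genes.tsv", "manifest.tsv", "beta.tsv", "samples.csv"]
    missing = [f for f in required if not (indir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"study directory {indir} is missing inputs: {missing}")
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t",
                           dtype={"probe_id": str, "chrom": str})
    data = StudyData(
        genes=eio.read_gene_models(indir / "genes.tsv"),
        manifest=manifest,
        beta=eio.read_beta_matrix(indir / "beta.tsv", manifest=manifest),
        sheet=eio.read_sample_sheet(indir / "samples.csv"),
    )
    optional = {"expression": "expression.tsv", "k4me1": "k4me1.bed",
                "k27ac": "k27ac.bed", "k36_ref": "k36_reference.bed",
                "k36_pert": "k36_perturbed.bed"}
    for attr, fname in optional.items():
        path = indir / fname
        if path.exists():
            if fname.endswith(".bed"):
                setattr(data, attr, read_bed(path, merge=True))
            else:
                setattr(data, attr, eio.read_expression(path))
    return data


def _write_summary(summary: dict, outdir: Path, config: PipelineConfig) -> None:
    summary["config_hash"] = config.hash()
    summary["seed"] = config.seed
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float))


# ---------------------------------------------------------------------
# cell-line workflow
# ---------------------------------------------------------------------

def run_cellline_analysis(data: StudyData, config: PipelineConfig,
                          outdir=None) -> dict:
    """Isogenic cell-line workflow (parental vs KO clones).

    Pooled delta-beta (condition group means) feeds classification,
    feature enrichment, enhancer stratification, K36 quadrants and tier
    contingencies; DMRs are additionally called per KO clone (each
    perturbed sample vs the pooled reference) and their conservation
    between the first two clones reported.
    """
    config.validate()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.delta_threshold_cellline
    log.info("cell-line analysis: %d probes, %d samples",
             len(data.beta), data.beta.shape[1])

    track = dm.compute_delta_beta(data.beta, data.sheet, grouping="condition")
    diff = dm.classify_diff_cpgs(track, thr)
    log.info("differential CpGs at |delta|>=%.2f: %d hyper, %d hypo",
             thr, len(diff.hyper), len(diff.hypo))
    hyper_frac = dm.hyper_fraction(diff) if diff.n_total else float("nan")
    enrich = dm.feature_enrichment(diff, data.manifest)

    man_idx = data.manifest.set_index("probe_id")
    diff_table = pd.DataFrame({
        "delta": track["delta"],
        "class": pd.Series("none", index=track.index, dtype=object),
        "feature": man_idx["feature"].reindex(track.index),
        "enhancer_class": man_idx["enhancer_class"].reindex(track.index),
    })
    diff_table.loc[diff.hyper, "class"] = "hyper"
    diff_table.loc[diff.hypo, "class"] = "hypo"
    diff_table.to_csv(outdir / "diff_cpgs.tsv", sep="\t",
                      index_label="probe_id")
    enrich.to_csv(outdir / "feature_enrichment.tsv", sep="\t")

    # per-clone DMRs + conservation
    pert_samples = list(data.sheet.index[data.sheet["condition"] == "perturbed"])
    clone_dmrs = {}
    for sample in pert_samples:
        sub_sheet = data.sheet[(data.sheet["condition"] == "reference")
                               | (data.sheet.index == sample)]
        clone_track = dm.compute_delta_beta(
            data.beta[list(sub_sheet.index)], sub_sheet, grouping="condition")
        clone_dmrs[sample] = dmr_mod.call_dmrs(
            clone_track, data.manifest, min_run=config.dmr_min_run,
            delta_min=config.dmr_delta_min)
    pooled_dmrs = dmr_mod.call_dmrs(track, data.manifest,
                                    min_run=config.dmr_min_run,
                                    delta_min=config.dmr_delta_min)
    dmr_mod.dmrs_to_bed(pooled_dmrs, outdir / "dmrs_pooled.bed")
    conservation = None
    if len(pert_samples) >= 2:
        a, b = pert_samples[0], pert_samples[1]
        conservation = dmr_mod.dmr_conservation(clone_dmrs[a], clone_dmrs[b])
        log.info("DMRs: %s=%d, %s=%d, conservation=%s",
                 a, len(clone_dmrs[a]), b, len(clone_dmrs[b]), conservation)

    # K36 integration
    summary: dict = {
        "mode": "cellline",
        "n_probes": int(len(data.beta)),
        "n_hyper": len(diff.hyper),
        "n_hypo": len(diff.hypo),
        "hyper_fraction": hyper_frac,
        "n_dmrs_pooled": len(pooled_dmrs),
        "n_dmrs_per_clone": {s: len(d) for s, d in clone_dmrs.items()},
        "dmr_conservation": conservation,
        "delta_threshold": thr,
    }
    genome_size = data.genome_size
    if genome_size:
        summary["k36_coverage_ref"] = k36_mod.genome_coverage_fraction(
            data.k36_ref, genome_size)
        summary["k36_coverage_pert"] = k36_mod.genome_coverage_fraction(
            data.k36_pert, genome_size)
    if len(data.k36_ref) or len(data.k36_pert):
        signals = k36_mod.gene_k36_signal(data.genes, data.k36_ref,
                                          data.k36_pert)
        gain, loss, sig_table = k36_mod.differential_k36_genes(
            signals, fc_threshold=config.fc_threshold,
            pseudocount=config.k36_pseudocount)
        sig_table.to_csv(outdir / "k36_gene_signal.tsv", sep="\t", index=False)
        gain_regions = PeakSet.from_arrays(
            *_region_arrays(data.k36_pert.subtract(data.k36_ref)))
        loss_regions = PeakSet.from_arrays(
            *_region_arrays(data.k36_ref.subtract(data.k36_pert)))
        quad = k36_mod.cpg_k36_quadrants(diff, gain_regions, loss_regions,
                                         data.manifest, alpha=config.alpha)
        quad.counts.to_csv(outdir / "k36_quadrant_counts.tsv", sep="\t")
        quad.labels.to_csv(outdir / "k36_quadrant_labels.tsv", sep="\t")
        summary.update({
            "n_k36_gain_genes": len(gain), "n_k36_loss_genes": len(loss),
            "quadrant_counts": {f"{d}_{r}": int(quad.counts.loc[d, r])
                                for d in ("hyper", "hypo")
                                for r in ("gain", "loss")},
            "quadrant_labels": {f"{d}_{r}": quad.labels.loc[d, r]
                                for d in ("hyper", "hypo")
                                for r in ("gain", "loss")},
        })
        peak_stats = k36_mod.peak_feature_stats(data.k36_ref, data.genes)
        peak_stats.to_csv(outdir / "k36_peak_stats_reference.tsv", sep="\t")
        k36_mod.peak_feature_stats(data.k36_pert, data.genes).to_csv(
            outdir / "k36_peak_stats_perturbed.tsv", sep="\t")

    # enhancer states and expression tiers
    if len(data.k4me1) or len(data.k27ac):
        smap = enh.classify_enhancer_states(data.k4me1, data.k27ac)
        enh_db = enh.enhancer_delta_beta(track, smap, data.manifest)
        enh_db.to_csv(outdir / "enhancer_delta_beta.tsv", sep="\t", index=False)
        if data.expression is not None and (len(data.k36_ref) or len(data.k36_pert)):
            tiers = enh.expression_tiers(data.expression, data.sheet,
                                         cutoff_rpkm=config.tier_cutoff_rpkm)
            up, down, fc = enh.expression_fold_change(
                data.expression, data.sheet, pseudocount=config.pseudocount,
                fc_threshold=config.fc_threshold)
            universe = list(data.expression.index)
            low_up = [g for g in up if tiers[g] == "low"]
            cont = enh.tier_epigenome_contingency(
                universe, low_up, gain, name_a="low_tier_up",
                name_b="k36_gain", alpha=config.alpha)
            cont["table"].to_csv(outdir / "tier_k36_contingency.tsv", sep="\t")
            summary.update({
                "n_up_genes": len(up), "n_down_genes": len(down),
                "n_low_tier": int((tiers == "low").sum()),
                "low_up_k36gain_overlap_p": cont["p_overlap"],
                "low_up_k36gain_label": cont["label"],
            })
            content = dmr_mod.dmr_gene_content(
                pooled_dmrs, data.genes, tiers=tiers, fold_change=fc,
                fc_threshold=config.fc_threshold)
            content.to_csv(outdir / "dmr_gene_content.tsv", sep="\t",
                           index=False)
    _write_summary(summary, outdir, config)
    return summary


def _region_arrays(ps: PeakSet):
    df = ps.df
    return df["Chromosome"].to_numpy(), df["Start"].to_numpy(), df["End"].to_numpy()


# ---------------------------------------------------------------------
# cohort workflow
# ---------------------------------------------------------------------

def run_cohort_analysis(cohorts: dict[str, StudyData], config: PipelineConfig,
                        outdir=None) -> dict:
    """Tumor-cohort workflow: per-cohort delta at the cohort threshold,
    top-variable-CpG clustering with genotype segregation, and (with >=2
    cohorts) the conserved hypermethylation signature."""
    config.validate()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.delta_threshold_cohort
    summary: dict = {"mode": "cohort", "cohorts": {}, "delta_threshold": thr}
    tracks: dict[str, pd.DataFrame] = {}
    for name, data in cohorts.items():
        counts = data.sheet["genotype"].value_counts()
        if counts.reindex(["WT", "MUT"]).fillna(0).min() < 2:
            raise ValueError(
                f"cohort {name!r} needs >=2 samples per genotype, "
                f"got {counts.to_dict()}")
        track = dm.compute_delta_beta(data.beta, data.sheet,
                                      grouping="genotype")
        tracks[name] = track
        diff = dm.classify_diff_cpgs(track, thr)
        n_top = min(config.top_n_variable, len(data.beta.dropna(axis=0)))
        probes = clu.top_variable_cpgs(data.beta, n=n_top)
        labels = clu.two_cluster(data.beta.loc[probes])
        seg, chi2_p = clu.genotype_segregation(labels, data.sheet["genotype"])
        labels.to_frame().assign(genotype=data.sheet["genotype"]) \
            .to_csv(outdir / f"clusters_{name}.tsv", sep="\t")
        summary["cohorts"][name] = {
            "n_samples": int(data.beta.shape[1]),
            "n_hyper": len(diff.hyper), "n_hypo": len(diff.hypo),
            "hyper_fraction": (dm.hyper_fraction(diff)
                               if diff.n_total else None),
            "n_top_variable": n_top,
            "segregation_percent": seg,
            "chi2_p": chi2_p,
        }
        log.info("cohort %s: segregation %.1f%% (chi2 p=%.3g)",
                 name, seg, chi2_p)
    if len(cohorts) >= 2:
        sig = clu.conserved_hyper_signature(tracks, n_sig=config.n_signature)
        sig.per_cohort_delta.to_csv(outdir / "signature_probes.tsv", sep="\t",
                                    index_label="probe_id")
        summary["signature_size"] = len(sig.probes)
    _write_summary(summary, outdir, config)
    return summary


# ---------------------------------------------------------------------
# synthetic benchmark
# ---------------------------------------------------------------------

def run_synthetic_benchmark(config: PipelineConfig, outdir=None,
                            n_cohort_seeds: int = 5) -> dict:
    """Generate synthetic data, run both workflows, score recovery.

    Cell-line scores: planted-probe recovery, null false-positive rate,
    hyper fraction, DMR block sensitivity and false count, DMR
    conservation between simulated clones, K36 coverage change.  Cohort
    scores: genotype segregation (median over ``n_cohort_seeds`` seeds)
    and signature purity (fraction of signature probes truly planted).
    """
    config.validate()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- cell-line arm ---
    syn = SyntheticConfig.cellline(seed=config.seed)
    study = simulate_study(syn)
    data = StudyData.from_study(study)
    cell_dir = outdir / "cellline"
    summary_cell = run_cellline_analysis(data, config, outdir=cell_dir)
    truth = study.truth

    track = dm.compute_delta_beta(data.beta, data.sheet, grouping="condition")
    diff = dm.classify_diff_cpgs(track, config.delta_threshold_cellline)
    planted = set(truth.planted_probe_ids)
    hyper = set(diff.hyper)
    null_probes = [p for p in track.index
                   if p not in planted and truth.mu_ref[p] == truth.mu_pert[p]]
    metrics = {
        "planted_probe_recovery": len(planted & hyper) / len(planted),
        "null_fpr": sum(p in hyper for p in null_probes) / len(null_probes),
        "hyper_fraction": summary_cell["hyper_fraction"],
        "dmr_conservation": summary_cell["dmr_conservation"],
        "k36_coverage_ref": summary_cell["k36_coverage_ref"],
        "k36_coverage_pert": summary_cell["k36_coverage_pert"],
    }
    pooled_dmrs = dmr_mod.call_dmrs(track, data.manifest,
                                    min_run=config.dmr_min_run,
                                    delta_min=config.dmr_delta_min)
    block_hit = 0
    dmr_probe_sets = [set(d.probe_ids) for d in pooled_dmrs]
    for block in truth.planted_blocks:
        bset = set(block["probe_ids"])
        if any(bset & s for s in dmr_probe_sets):
            block_hit += 1
    false_dmrs = sum(1 for s in dmr_probe_sets if not (s & planted))
    metrics["dmr_block_sensitivity"] = block_hit / len(truth.planted_blocks) \
        if truth.planted_blocks else None
    metrics["dmr_false_count"] = false_dmrs

    # --- cohort arm: one genome and truth, independent samples per seed ---
    from .simulate import generate_beta_cohort, generate_genome, plant_effects
    ccfg = SyntheticConfig.cohort(seed=config.seed)
    cgenes, cmanifest, _ = generate_genome(ccfg)
    ctruth = plant_effects(cgenes, cmanifest, ccfg)
    seg_values = []
    cohort_tracks: dict[str, pd.DataFrame] = {}
    for i in range(n_cohort_seeds):
        name = f"cohort{i + 1}"
        beta, sheet = generate_beta_cohort(
            cmanifest, ctruth, ccfg, cohort=name,
            noise_seed=config.seed + 100_003 * (i + 1))
        n_top = min(config.top_n_variable, len(beta))
        probes = clu.top_variable_cpgs(beta, n=n_top)
        labels = clu.two_cluster(beta.loc[probes])
        seg, _ = clu.genotype_segregation(labels, sheet["genotype"])
        seg_values.append(seg)
        cohort_tracks[name] = dm.compute_delta_beta(beta, sheet,
                                                    grouping="genotype")
    metrics["segregation_percent_median"] = float(np.median(seg_values))
    metrics["segregation_percent_all"] = seg_values
    if len(cohort_tracks) >= 2:
        sig = clu.conserved_hyper_signature(
            {k: cohort_tracks[k] for k in list(cohort_tracks)[:3]},
            n_sig=config.n_signature, threshold=config.delta_threshold_cohort)
        cplanted = set(ctruth.planted_probe_ids)
        metrics["signature_size"] = len(sig.probes)
        metrics["signature_purity"] = (
            sum(p in cplanted for p in sig.probes) / len(sig.probes)
            if sig.probes else None)
    (outdir / "benchmark_metrics.json").write_text(
        json.dumps(metrics, indent=1, default=float))
    metrics["config_hash"] = config.hash()
    return metrics
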