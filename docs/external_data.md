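# Reproducing the published cohort statistics from deposited data

The headline percentages published for the SETD2 cell-line and tumor
datasets — >80% of |Δβ|≥0.2 CpGs hypermethylated in the 786-O KO clones,
~80% DMR conservation between the two KO clones, 86/83/79% genotype
segregation for TCGA KIRC/KIRP/LuCa, and 88% segregation on the 200-CpG
conserved signature — cannot be recomputed from this repository alone:
they require the deposited 450K array data (GEO **GSE70645**, plus the
NCCIT control **GSM1527531** in **GSE54840**) and TCGA KIRC/KIRP/LUAD
450K + mutation calls, none of which are redistributable here.  The
synthetic benchmark (`epishift benchmark`) exercises the identical code
paths on simulated data instead.

Given the downloads, the exact commands are below.  Each study directory
must contain the package's file dialects: `beta.tsv` (probe × sample
beta values), `samples.csv` (sample_id, condition, genotype, cohort),
`manifest.tsv` (probe_id, chrom, pos, feature, enhancer_class,
nearest_gene — derivable from the Illumina manifest with
`epishift.annotate_probes`), `genes.tsv` (BED6 gene models), and
optionally H3K36me3 / H3K4me1 / H3K27ac peak BEDs.

## 786-O parental vs SETD2 KO1/KO2 (GSE70645)

```sh
# hyper fraction at |dbeta| >= 0.2, per-clone DMRs and their conservation
epishift run-cellline --indir data/gse70645_786o --outdir results/786o
# summary.json fields: hyper_fraction, n_dmrs_per_clone, dmr_conservation
```

## NCCIT SETD2 siKD vs control (GSE70645 + GSM1527531)

```sh
# acute-depletion comparison uses the cohort threshold 0.1
epishift diffmeth --indir data/nccit_sikd --outdir results/nccit \
    --threshold 0.1 --grouping condition
```

## TCGA KIRC / KIRP / LuCa cohorts

```sh
# per-cohort delta at 0.1, top-10,000-variable-CpG clustering with
# genotype segregation, and the conserved 200-CpG signature
epishift run-cohort \
    --indir data/tcga_kirc --indir data/tcga_kirp --indir data/tcga_luca \
    --outdir results/tcga
# summary.json fields: cohorts.<name>.segregation_percent, chi2_p,
# hyper_fraction, signature_size; signature_probes.tsv lists the panel
```

Re-clustering all samples on the signature probes and re-running
`epishift.genotype_segregation` gives the signature-level segregation
percentage.
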