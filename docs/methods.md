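# Methods

## Scope and data model

`epishift` analyses the epigenomic phenotype of SETD2 loss-of-function:
DNA-methylation (beta-value) arrays, H3K36me3 / H3K4me1 / H3K27ac peak
intervals, gene models and RPKM expression tables, compared between a
reference condition (parental cells, SETD2-wild-type tumors) and a
perturbed one (knockout clones, siRNA depletion, SETD2-mutant tumors).

All coordinates are 0-based half-open (BED semantics); probes are
single-bp points.  Probe features are derived from gene models as

* promoter = TSS ± 1,500 bp,
* 3′-terminus = TES ± 1,500 bp clipped to the gene span on the interior
  side,
* body = the remaining gene span,

with the precedence promoter > terminus > body > intergenic when
windows of short genes overlap.  The window half-widths are
config-exposed; they are declared defaults, not values recovered from
data (published analyses of this design do not state theirs).  A probe
with any missing beta value is dropped from statistics that need all
samples; nothing is imputed.

## Differential methylation

Δβ is the difference of group means, perturbed minus reference,
computed per probe with per-group missing-value exclusion.  Cell-line
analyses compare each knockout clone to the pooled reference
(singleton perturbed groups are allowed); cohort analyses compare
genotype groups (MUT vs WT) by group means — means rather than medians
is an assumption, config-free, noted here because either convention
appears in the literature.

Differential CpGs are threshold calls, not hypothesis tests: |Δβ| ≥ 0.2
(cell line) or ≥ 0.1 (cohort), closed comparisons, partitioned by sign.
This mirrors how such sets are defined for 450K comparisons of isogenic
lines, where 2–3 samples per arm make per-probe testing underpowered; a
two-sided rank-sum p per probe is available separately for cohort
volcano plots (exploratory only, no multiplicity correction).

Feature-normalised enrichment divides the feature composition of a
differential set by the array's background composition; ratios
therefore average to 1 under the background weighting (mass
conservation), which the tests assert.  Metagene profiles map each
probe to a strand-oriented fractional coordinate (0 = TSS, 1 = TES)
with flanks of 25% gene length and 100 bins; genes are averaged with
equal weight after per-gene binning so long genes do not dominate.

## DMR calling

A DMR is a maximal run of at least `min_run` = 8 consecutive probes —
consecutive in array order on one chromosome — each individually
passing Δβ ≥ `delta_min` = 0.2.  The per-probe rule (rather than a
run-mean rule) is the strict reading of the definition; a probe with no
Δβ breaks contiguity; `max_gap` (default unlimited) optionally breaks
runs across probe deserts.  Hypomethylated DMRs (Δβ ≤ −0.2) are
supported behind a flag but off by default.  Conservation between two
DMR lists is the fraction of DMRs in the first sharing ≥ 1 probe with
any DMR of the second (bp-overlap and reciprocal-fraction criteria are
config alternatives); an empty first list yields an undefined result
(`None`), distinct from 0.

## H3K36me3 integration

Genome coverage is merged-peak bp over genome size.  Peaks are assigned
to the feature containing their midpoint (a peak can span features; the
midpoint is the documented tie-break).  The per-gene signal is the
peak-covered fraction of the gene span — a documented stand-in for
read-count-based differential enrichment when only peak intervals are
available; with binned coverage tracks the bp-weighted mean is used
instead.  Differential genes satisfy |log2((s′+c)/(s+c))| ≥ 1 with
pseudocount c = 0.01 signal units (config-exposed).

Differential CpGs falling in regions that gained or lost the mark form
a 2×2 quadrant table (direction × region type).  Per-cell significance
uses the EASE-modified Fisher exact test against the background of all
array probes inside any differential region: overlap = one-tailed
enrichment with the EASE decrement; exclusion = one-tailed depletion
*without* the decrement, since decrementing the observed count would
anti-conservatively inflate depletion significance.

## The EASE-modified Fisher exact test

For an overlap of k elements between an n-set and a K-set in a universe
of N, the EASE score replaces k by k′ = max(k − 1, 0) before the
hypergeometric computation.  One-tailed enrichment is P(X ≥ k′);
two-tailed sums all point masses not exceeding pmf(k′) (the standard
minimum-likelihood convention, with a 1 + 1e−7 relative guard against
floating-point ties).  If the decrement pushes k′ below the support of
the distribution the p-value is 1.  EASE enrichment p ≥ plain Fisher
enrichment p for every valid table (conservatism), a property the test
suite checks exhaustively for N ≤ 30.

## Enhancer states and expression

H3K4me1 and H3K27ac peak sets are partitioned at bp level into
K4me1-only ("poised"), K4me1+K27ac, and K27ac-only intervals; the three
parts exactly tile the union of the marks.  Genes receive one label
from the states intersecting their span ± 10 kb (the flank is a
declared default); genes touched by all three state classes are
labelled `all_classes` and excluded from three-way comparisons by
default.  Δβ stratified by state × feature pools probes per probe, not
per peak.

Expression tiers split on mean reference RPKM at a cutoff of 1
(config-exposed; zeros are low tier), and fold changes are
(mean′ + 0.01)/(mean + 0.01) with up/down at ≥ 2 and ≤ 0.5.  Tier ×
epigenome contingencies are 2×2 tables over the gene universe with
EASE overlap, plain depletion, and two-tailed p-values.

## Clustering and signatures

Samples are clustered on the top 10,000 most-variable CpGs (sample
variance, ddof = 1; ties broken lexicographically by probe id; probes
with missing values excluded) with Euclidean average-linkage
agglomerative clustering, cut at the root into two clusters.  Distance
and linkage are config-exposed — published heatmap analyses of this
kind rarely name them — and the defaults are the most common choice for
beta-value matrices.  Segregation orients the two clusters to the
genotype (so it is ≥ 50% by construction) and reports the concordant
percent plus a Yates-corrected 2×2 chi-square p.

The conserved hypermethylation signature takes probes hypermethylated
in every cohort and ranks them by their minimum Δβ across cohorts,
descending — the probes whose weakest cohort is still strongest — and
keeps the top 200.  "Most conserved" has no canonical ranking
statistic; min-across-cohorts is this package's definition.

## Synthetic data generator

The generator emulates the study's structure, not its genome scale:

* 2 chromosomes × 5 Mb, 200 genes (5–40 kb) tiled with intergenic gaps,
  drawn gaps rescaled so the tiling always fits; ~23,000 probes with
  exponential spacing (mean 500 bp) plus 3× density in promoter
  windows, mimicking the promoter-heavy composition of 450K arrays.
* Half the genes are expressed ("high" tier): their bodies and termini
  carry reference H3K36me3 peaks and a distal (4–9 kb upstream) 2-kb
  H3K27ac enhancer, half of those also K4me1.  A configured fraction of
  silent genes carries a distal K4me1-only element — the poised-
  enhancer compartment.
* Baseline mean betas: promoters 0.10, poised enhancers 0.15, active
  enhancers 0.05, expressed gene bodies/termini 0.80, silent bodies and
  intergenic space 0.50 (intermediate).
* Perturbed condition: 50 planted hypermethylation blocks of 25
  consecutive eligible probes (~12 kb domains; eligible = intergenic or
  silent-gene loci, never active enhancers or expressed genes), shifted
  up by Δβ = 0.25 (cell-line mode) or 0.15 (cohort mode); about half
  the blocks are drawn from runs containing poised probes, making
  poised enhancers preferred targets.  60% of expressed genes lose
  their gene-body H3K36me3; 30 of them also lose 0.2 (cell line) /
  0.12 (cohort) of terminus methylation.  60% of planted blocks gain an
  ectopic H3K36me3 peak, and silent genes under those peaks get a
  4-fold perturbed expression up-shift (floored so the pseudocount
  fold change clears 2).
* Measurement noise: each sample's beta is Beta(μκ, (1−μ)κ) around the
  true mean μ, κ = 100 (cell line, 3 samples/arm) or 60 (cohort, 20
  samples/arm).  The bounded support is the only clipping.  Expression
  adds log-normal noise (σ = 0.2 log units); 30% of silent genes are
  exact zeros to exercise the pseudocount path.

Everything is deterministic under one seed (per-stage child streams
from a `SeedSequence`), and a truth table records planted blocks,
ectopic regions, K36-losing genes, terminus-hypo genes, up-shifted
genes and the per-probe true means, so recovery can be scored from
emitted files alone.

What the generator does *not* model: probe-type (Infinium I/II)
chemistry, cross-reactive or SNP probes, tumor purity and cellular
heterogeneity, copy number, read-level ChIP noise, or correlated
(sample-level) array effects — planted-effect recovery rates on this
synthetic data therefore bound what the same thresholds would achieve
on real arrays from above.  At the cell-line noise level the per-probe
recovery of a planted +0.25 block probe at the 0.2 threshold is ~90%
(the Δβ of a true 0.25 shift has an sd of ~0.04 with three samples per
arm), which is why DMR-level recovery uses 25-probe blocks: a ≥ 8-run
survives probe-level dropout with ~90% probability at that length.
Between simulated singleton clones (one KO sample vs the pooled
reference) DMR conservation is ~60–70%, noticeably below what pooled
comparisons give — per-clone Δβ carries ~1.5× the noise.

## Problem sizes and reproducibility

Test-suite and acceptance runs use the generator defaults above
(~23,000 probes, 200 genes, 3 or 20 samples per arm, 20 cohort seeds
for the segregation summary) — sizes chosen so a desk run of the whole
suite stays in tens of seconds while every rate being asserted has a
few hundred to a few thousand events behind it.  Workflow summaries
embed the seed and a hash of the analytic configuration (paths
excluded); provenance is centralised in `summary.json` rather than
repeated in every TSV header.

## Known limitations

* The per-gene H3K36me3 signal from peak intervals collapses amplitude
  information; SICER-style read-count fold changes on real data will
  rank genes somewhat differently.
* Cohort Δβ uses genotype-group means; medians would be more robust to
  outlier tumors but are not what the threshold conventions above were
  built around.
* The conserved-signature ranking (min Δβ across cohorts) is one of
  several defensible "most conserved" definitions; rankings near the
  200-probe cut are sensitive to it.
* `dmr_conservation` is undefined (not 0) when the first list is
  empty; callers must handle `None`.
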