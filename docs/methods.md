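# Methods

`swabmark` reimplements, as a tested library, a swab-based mRNA biomarker
workflow for oral/oropharyngeal squamous cell carcinoma: RNA-seq candidate
discovery with a robust fold-change filter cascade, RT-qPCR ΔCt validation,
and combinatorial marker-panel ROC analysis. Because the underlying patient
data are unpublished, the package ships a synthetic cohort generator that
emulates the study's data structure; every statistical claim the test suite
makes is about the machinery, verified on data with known ground truth.

## Discovery statistics

Counts are depth-normalised by median-of-ratios size factors: per gene the
reference is the geometric mean across samples (genes containing any zero
are excluded from the reference), and a sample's factor is the median ratio
of its counts to the reference. Technical replicates are summed into one
column per biological sample before analysis; sample QC drops libraries
with fewer than `min_assigned` total counts (default 10,000, suited to the
simulated depth) or with a median replicate coefficient of variation above
`max_replicate_cv` (default 0.5) across expressed genes. The source
workflow assessed replicate deviations qualitatively; the CV rule here is
this package's operational definition.

The per-gene differential test is a deliberate stand-in for a
negative-binomial Wald model: a two-sided Welch t test on
log2(normalised count + 1), with Benjamini–Hochberg adjustment across all
genes of a contrast. The discovery contract downstream is the filter
cascade, which consumes base means and fold changes and does not depend on
the flavour of the per-gene test. The +1 pseudocount bounds behaviour at
zero counts. On simulated null cohorts (4 vs 6 samples) the test is mildly
conservative (rejection rate ≈ 0.045 at α = 0.05), a familiar property of
t tests on log counts at this sample size; the acceptance suite checks the
rate against the exact binomial 99% band.

PCA is computed on log2 normalised counts, gene-centred, samples as
observations, without gene-variance scaling (common RNA-seq QC practice);
variance explained comes from the singular values.

## Robust fold change and the filter cascade

For a tumour-up candidate the robust ("largest minimum") fold change is
`min(tumour) / max(healthy)` on normalised counts — the worst-case
separation ratio; a value above 1 means every tumour sample exceeds every
healthy sample. This pairs the least-expressing case with the
highest-expressing control, favouring markers that remain detectable in
every patient rather than only on average.

Candidates (adjusted p < 0.05 and over-expressed in the healthy-vs-tumour
contrast; an intersection over the smoking-stratified contrasts is
available) pass through, in order: overall base mean > 25; log2FC > 2;
tumour-minus-healthy base-mean difference within [50, 3500] (inclusive,
high enough to be RT-qPCR-robust, low enough not to saturate); and at most
one outlier per group. Strictness of each inequality follows the published
thresholds. "Outlier" is defined here (the source workflow left it
informal): the separation threshold t\* is the geometric mean of the two
group medians, and a tumour sample below t\* or a healthy sample above t\*
counts as discordant. Survivors are ranked by robust fold change, ties
broken by gene identifier.

## RT-qPCR quantification

Triplicate Ct wells are averaged per (sample, gene); if the replicate SD
exceeds `max_sd` (default 0.5 cycles, a common triplicate-concordance
threshold — the source protocol states none) the single well whose removal
minimises the SD is dropped, and the row is flagged `rescued` if the
remaining pair agrees, `high_sd` otherwise; fewer than two usable wells
leave the row missing. ΔCt = target Ct − housekeeping Ct (MT-ATP6 by
default); relative expression is 2^−ΔCt and all statistics are computed on
log2 relative expression (= −ΔCt), where Gaussian assumptions are
reasonable; fold changes are reported on the linear scale as ratios of mean
relative expression. Group comparisons are two-tailed Welch t tests.
Missing Ct values are encoded as empty/"NA", never as a sentinel cycle
number — Ct 40 is a legitimate measurement.

## ROC and panel analysis

AUC is the Mann–Whitney statistic (ties counted ½), computed from midranks;
the ROC curve is evaluated on the grid of unique scores plus ±∞ sentinels
with "positive" meaning score ≥ threshold, so the trapezoidal area equals
the pair-counting AUC exactly. The operating point maximises the Youden
index J = SE + SP − 1, ties resolved toward the smaller cutoff; false
positives/negatives are also reported as percentages of the whole evaluated
cohort. Evaluation is in-sample, as in the source workflow — reported
accuracies are therefore optimistic for new cohorts, and no multiplicity
correction is applied across panel combinations (the report notes this).

Panels enumerate every marker subset of sizes 2–4. The default combined
score is the in-sample predicted probability of an L2-penalised logistic
model on standardised log2 relative expression (ridge weight 1e-6 —
effectively unpenalised, the ridge only stabilises separable fits); this
mirrors GLM-based panel tools and puts the cutoff on a probability scale.
A `mean_z` alternative (mean of per-marker z-scores) is provided for
transparency. Constant markers are dropped with a warning. Ranking is by
AUC, then Youden J, then smaller panel size.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested.

Discovery counts: 4 male tumour patients, 3 healthy smokers, 3 healthy
non-smokers, 2 technical replicates each; 2000 genes of which 40 are tumour
markers (planted log2FC 3 in tumour) and 40 smoking-responsive (log2FC 2 in
smokers; tumour subjects are smokers, as in the source cohort). Counts are
negative binomial with variance μ + αμ², a single global dispersion
α = 0.1 (typical bulk RNA-seq overdispersion; per-gene dispersion is a
config extension point), and per-library log-normal depth (σ = 0.2 on the
natural-log scale). Baseline means are log2-uniform on [1, 9]; marker genes
are drawn from the mid-range band [4.5, 7.0] because diagnostic candidates
are by construction mid-abundance transcripts — the published base-mean
difference window [50, 3500] is unsatisfiable for genes near the noise
floor, and the recovery tests exercise the cascade under conditions it is
meant for.

Validation Ct table: four clinical groups (healthy, tumour, post-therapy,
high-risk) by sex at the published cohort sizes — males 12/14/12/11,
females 19/11 (79 samples; where the source text and its cohort table
disagree on the female split, the table's 19/11 is used). True
Ct = 20 − log2(relative abundance); gene baselines are log2-uniform on
[−8, −3] relative to the housekeeping gene (ΔCt 3–8, a typical qPCR
range). Tumour samples of marker genes gain the planted effect,
multiplied by 0.3 in females (a tunable scenario reproducing the weaker
female discrimination structurally, not a biological estimate).
Subject-level biological noise of 1.0 log2 units is added per (sample,
gene) — without it groups would separate deterministically and every AUC
would be exactly 1. Triplicate wells add iid N(0, 0.15²) cycler noise;
with probability 0.02 a (sample, gene) pair is shifted ±4 cycles (sign
symmetric, so effect estimates stay unbiased) and recorded in the ground
truth. Post-therapy and high-risk groups sit at healthy baseline.

What the generator does not emulate: gene–gene correlation, per-gene
dispersion, amplification-efficiency differences between assays, batch or
plate effects, field cancerization in contralateral swabs, and any HPV
effect. Passing tests therefore demonstrate correctness of the machinery
under a clean generative model, not clinical performance.

Randomness: one PCG64 stream per artifact (baselines, counts, Ct,
outliers), spawned from the master seed, so adding an artifact never
perturbs the others; identical configuration implies byte-identical
outputs.

## Numerical and design notes

- Robust FC orientation follows the prose definition (worst tumour vs best
  healthy for tumour-up markers); the displayed formula in the source reads
  inverted and is not recoverable exactly.
- The candidate set defaults to the single all-healthy-vs-tumour contrast;
  an intersection across smoking-stratified contrasts is a switch.
- Welch p-values for genes constant in both groups are set to 1 (no
  evidence, 0/0 statistic).
- A pseudocount is applied inside `robust_fold_change` only when zeros are
  present, keeping the statistic scale-equivariant on positive data.
- The config hash excludes the output directory: where artifacts land does
  not change what was computed.
- Problem sizes in the test suite (e.g. 50-seed recovery runs, 10-cohort
  null calibration, 2000 genes) are chosen as the smallest scales at which
  the Monte-Carlo error is comfortably below the tested margins.

## Known limitations

In-sample panel evaluation overstates transportable accuracy (a
leave-one-out flag exists but is off by default to match the source
workflow conceptually). The Welch stand-in is not DESeq2 and its p-values
will differ from an NB Wald test, especially at low counts. The outlier
and replicate-CV rules are this package's operational definitions of rules
the source workflow applied informally. Cohort-level published numbers
(e.g. specific AUCs) are not reproducible without the unpublished data;
the test suite instead verifies the machinery against oracles and planted
ground truth.
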