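# Methods

This note documents the statistical models behind each pipeline stage, the
synthetic data they are validated on, and the numerical and design choices
made where the procedure was genuinely open.

## Detection-probability differential expression

Single-cell UMI counts from multiple patient cohorts are too heterogeneous
(platforms, depth, ambient RNA) for cell-level tests, and the outcome of
interest — disease status — varies at the patient level.  The pipeline
therefore collapses each (sample, cell type) group to a per-gene detection
probability: the fraction of cells whose count exceeds a threshold τ.  Both
readings of "detected" are supported: τ = 0 (count ≥ 1, the default — the
natural meaning of detection in UMI data) and τ = 1 (count > 1, a stricter
variant); results carry the threshold used.  Because the response is a
probability in [0, 1], it is square-root transformed before ordinary least
squares on

    sqrt(p̂) ~ outcome + log10(total UMI) + log10(n cells) + cohort + age + gender

with the outcome column (disease or gender) removed from the covariate list
when it is the response of interest.  UMI and cell-count covariates enter on
the log₁₀ scale because both are heavily right-skewed; total UMI and cell
count are the *sample-level* totals.  Covariate columns that are constant
across the rows of a cell type (e.g. identical cell counts in a balanced
simulation) carry no information and are dropped rather than tripping the
rank check.  Cell types with fewer than 3 samples per outcome level, or a
rank-deficient design (e.g. disease perfectly confounded with cohort), are
skipped with a named reason.  A gene with identical detection in every
sample is reported with coefficient 0 and p = 1; an exact nonzero fit is
reported with a capped |t| of 10⁶ and p = 0.  OLS is implemented as a single
vectorized solve per cell type (one shared design, thousands of response
columns); it reproduces a closed-form (XᵀX)⁻¹Xᵀy oracle to 10⁻⁸ in t.
Multiple testing uses Benjamini–Hochberg within cell type
(`scipy.stats.false_discovery_control`); cross-cohort concordance is the
Pearson correlation of t-vectors over genes tested in both runs, flagged as
undefined below 3 shared genes.

## Signed-KS signature scoring

Signatures are scored against a ranked list by a *two-sample* KS test of
signature members' scores versus all other items (not one-sample against
uniform ranks), because the background distribution of real ranked
statistics is far from uniform.  The signed score is −log₁₀(p) carrying the
sign of mean(signature) − mean(background); the mean difference is the
simplest orientation-consistent effect-size definition and is the documented
convention here.  p-values come from `scipy.stats.ks_2samp`: exact for
signatures under 20 members, asymptotic otherwise (`method="auto"`); p is
floored at 10⁻³⁰⁰ before the log.  The asymptotic p agrees with a
10,000-draw permutation p within Monte-Carlo error for signature sizes ≥ 20
(checked in the acceptance suite against an independently coded exact
lattice-path oracle).  Signature items absent from the list are dropped and
counted; an empty intersection yields a flagged undefined score.  Signature
*derivation* is a one-vs-rest detection regression per cell type: genes with
BH-adjusted p < α and positive coefficient, capped by |t| — the derivation
rule is a documented reconstruction, since published marker tables rarely
state their exact thresholds.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions used everywhere.

* **Counts**: negative binomial (Gamma–Poisson) with per-gene lognormal
  baseline means (median 0.3 per cell), per-cell lognormal library factors
  (log-sd 0.3), per-cohort depth multipliers (1.0 / 0.6 / 1.5), and an
  8-fold marker elevation for 20 markers per cell type.  Dispersion r = 1.5.
* **Disease effects are planted on the detection scale**: for
  disease-responsive genes in ILD cells of the target type, the per-cell
  NB zero probability is adjusted (zeros promoted to ones, or detected
  counts zeroed) so the detection probability shifts by exactly ±δ in
  expectation.  This makes the detection-DE stage's estimand known in closed
  form (P(count > 0) = 1 − (r/(r+μ))ʳ).
* **Sex-linked genes** split half male-specific, half female-specific
  (Y-gene / XIST-like, 20-fold), which keeps total depth balanced between
  genders — an unbalanced design would make total UMI collinear with the
  gender outcome.
* **Proportions**: Dirichlet (concentration 60) over four baseline types;
  each ILD sample carries a latent fibrosis burden b ~ U(0.4, 1) that
  multiplies the AT2-like concentration by (1 − 0.5b) and adds a
  disease-only state (aberrant-basaloid analog, mean proportion 0.06 at mean
  burden, Beta-distributed) that controls never show.
* **Proteome**: 60% of proteins map to a marker gene of a source cell type
  and share its identifier (creating the cross-modal vocabulary overlap);
  log₂ intensity = α + β·z(source-type proportion) + γ·δ·b + ε with β = 3,
  noise sd 0.8.  Dropout is MNAR: P(missing) falls logistically with
  intensity (50% at the 8th intensity percentile).
* **Clinical**: DLCO/FVC/FEV1/TLC percent-predicted decline linearly in
  burden (e.g. DLCO = 90 − 45b + N(0, 5)); plasma LDH rises with burden;
  lung-function cells are MCAR at 5%.

What it deliberately does **not** emulate: ambient RNA, doublets, batch
effects beyond depth, protein–protein interactions, nonlinear
dose–response, or realistic gene–gene correlation structure outside planted
modules.  Passing recovery tests therefore demonstrates that each stage
estimates what it claims under its own model assumptions — not that those
assumptions hold in any particular real dataset.

## QC and consensus HVGs

Cell filters: ≥ 200 detected genes, < 4000 total UMIs (strict, a doublet
guard), ≤ 10% mitochondrial counts (gene ids matched by a configurable
prefix, default `MT-`); genes must be expressed in ≥ 3 cells.  Cells failing
several criteria are attributed to the first failing one (genes → UMI →
mito) so report counts add up.  Normalization is log1p of counts scaled by
per-cell size factors (totals scaled to mean 1); a pooled-deconvolution
estimator can be substituted via the `size_factors` argument.  Per-sample
highly-variable genes are the top 4,000 by normalized dispersion (var/mean
of log-normalized expression, z-scored within mean bins; bins capped so each
holds ≥ 20 genes; boundary ties kept, so slightly more than 4,000 can
qualify).  Consensus: HVG in ≥ 2 samples (sample level), or HVG in ≥ 3
patients of a cohort and then in ≥ 2 cohorts (cohort level).  Covariate
regression of UMI/mito/cell-cycle and ambient-RNA correction are outside the
tested surface; the ambient pCut value is carried in config for provenance
only.

## Meta lung function and imputation

The meta-lung-function score is PC1 of the standardized lung-function
columns, computed under missing data by EM: missing cells start at column
means; each sweep re-standardizes, reconstructs with a rank-1 SVD, and
refreshes the missing cells, until the largest change drops below 10⁻⁶
(configurable; 200-iteration cap with a hard error on non-convergence).  On
a complete table this is exactly PC1; a matrix whose complete version is
rank-1 is completed exactly.  The sign is fixed so the DLCO-like anchor
column loads positively — larger score = better lung function.  Protein
imputation is iterative per-protein regression on all other proteins
(`sklearn.impute.IterativeImputer`), nonparametric by default (small random
forests, seeded); a Bayesian-ridge estimator is available for large screens
and is what the multi-seed acceptance loops use.  Proteins with < 3 observed
values fall back to their median and are flagged.

## Cross-modal transfer

Quantile normalization forces each sample onto the mean-of-sorted-columns
reference, averaging ties; features are then z-scored across samples.  The
transfer model keeps proteins with |r| > 0.2 against DLCO whose identifiers
(case-insensitive) occur in the single-cell gene vocabulary, and fits a
random forest (500 trees by default, seeded).  At prediction time the bulk
table is restricted to the model features and quantile-normalized and scaled
*within its own modality* — no shared reference across modalities is needed,
only the rank structure; the training quantile reference is stored so a
map-to-training-quantiles variant can be built if wanted.  In-silico bulk is
the per-sample mean raw count over all cells.  Whether real bulk RNA-seq
should be log-transformed first is absorbed by quantile normalization's rank
invariance and is left off by default.

## Meta-cells and trajectories

The default clustering backend is PCA → kNN graph → Leiden, with the
resolution bisected until the cluster count lands within ±20% of the target
(default 50); any labeling or clustering callable can be substituted, which
is how tests use k-means for determinism and speed.  Clusters below the
minimum size (default 5) merge into the nearest cluster by centroid
distance.  Correlations are Pearson over cluster averages of log-normalized
expression (correlating on the log-normalized rather than scaled scale is
the documented choice); the guaranteed invariant is the law of total
variance — the *size-weighted* variance of cluster means never exceeds the
cell-level variance.  Pseudotime is consumed as a plain per-cell array from
any external routine (diffusion pseudotime in practice; the planted latent
in tests).  "Equally sized bins" is read as equal-count (robust to
pseudotime density; sizes differ by ≤ 1, stable ordering breaks ties), and
the smooth fit is a centered moving average (window 3, shrunk at the
endpoints) — a deliberately simple, parameter-transparent smoother.

## Problem sizes and acceptance conditions

The acceptance checks run the pipeline at: null calibration with 30
samples/arm × 2,000 genes; power with δ = 0.2, 20 samples/arm × 200
cells/sample; deconvolution over 100 seeds of 10-samples/arm mixtures;
classifier null/recovery with 20 samples/arm over 20 seeds (200 trees);
transfer over 50 seeds of 3 cohorts × 8 samples (60–80 cells, 600 genes,
150 proteins) with staged cohorts of 3 stages × 12 samples at burdens
0.15/0.55/0.95 — stages span minimal to severe fibrosis, and 12 samples per
stage keep the stage-median readout driven by the planted effect rather
than by Dirichlet sampling noise of per-sample composition; meta-cell gain
over 50 seeds of 300 cells × 40 genes.  The full suite and the acceptance
script each finish in minutes on one CPU.

## Known limitations

* The detection regression treats detection fractions as homoskedastic
  after the sqrt transform; groups with very few cells get no extra
  down-weighting beyond the optional minimum-cell floor.
* ELF scoring uses a reconstruction (z-scored log-ratio of median relative
  abundances, half-minimum substitution for one-sided proteins) — the
  underlying studies publish no equation for this quantity.
* The CV filter's threshold is data-dependent; the default (upper-quartile
  CV) is a convention, not an estimate.
* Protein↔gene matching by uppercase symbol equality ignores isoforms and
  protein groups.
* The permutation null of the classifier re-runs the entire CV per
  permutation, which is honest but costly; permutation counts beyond ~100
  are slow at default tree counts.
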