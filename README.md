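# fibroscope

Integrative analysis of lung fibrosis across modalities: multi-cohort
single-cell RNA-seq of lung tissue and mass-spectrometry proteomes of
bronchoalveolar lavage fluid (BALF), tied together by patient-level clinical
lung function.  The package re-implements the full statistical pipeline of
such a study as a tested, reusable library, together with a linked
synthetic-data generator so every stage has a parameter-recovery test that
runs in seconds without patient data.

It is aimed at computational biologists working on interstitial lung disease
(ILD) or, more generally, on studies that need to connect cell-state changes
seen by single-cell transcriptomics with body-fluid protein biomarkers and
clinical outcomes.

## What it computes

**Detection-probability differential expression.** Disease status varies per
patient, not per cell, so differential expression is framed at the sample
level: for each sample *s* and cell type *c*, the detection probability of
gene *g* is

&nbsp;&nbsp;&nbsp;&nbsp;p̂<sub>s,c</sub>(g) = #{cells of type *c* in *s* with count > τ} / n<sub>s,c</sub>,&nbsp;&nbsp;τ ∈ {0, 1},

and √p̂ is regressed by OLS on the outcome (ILD status or gender) with
log₁₀ total UMI, log₁₀ cell count, study-cohort indicators, age and gender as
covariates.  The outcome coefficient's t and p values are the DE statistics;
p values are Benjamini–Hochberg adjusted within cell type.

**Signed-KS signature deconvolution.** A cell-type signature *S* is scored in
any ranked list r(g) (fold changes, correlations, group mean z-scores) by a
two-sample Kolmogorov–Smirnov test of {r(g): g ∈ S} against all background
items; the signed score is −log₁₀(p) · sign(mean<sub>S</sub> − mean<sub>bg</sub>),
so positive = enrichment, negative = depletion.

**Composition classifier.** A stratified-CV random forest on per-sample
cell-type proportions predicts disease status, with a label-permutation null
and fold-averaged feature importances.

**Cross-modal lung-function transfer.** Protein intensities are quantile
normalized and scaled; features with |Pearson r| > 0.2 against DLCO that are
also in the single-cell gene vocabulary train a random-forest regressor,
which is then applied to the quantile-normalized in-silico bulk transcriptome
(per-sample mean counts over all cells).

**Proteome/clinical statistics.** Min-patient and CV filters,
pairwise-complete protein–clinical correlations, a PCA-based "meta lung
function" score computed under missing clinical values by iterative-PCA (EM)
imputation, random-forest-style iterative protein imputation, per-protein
multivariate regression (meta lung function ~ protein + age + gender), and an
epithelial-lining-fluid vs tissue-leakage enrichment score.

**Meta-cell correlation & trajectories.** Cells are aggregated into small
clusters of transcriptionally similar cells before computing gene–gene
Pearson correlations (damping UMI sparsity), with a cross-cohort
same-direction consensus; expression along an externally supplied pseudotime
is averaged in equal-count bins and smoothed with a short moving average.

## Worked example

`examples/` contains one short script per capability.  For instance the
cross-modal transfer (`python examples/05_crossmodal_transfer.py`) trains on
simulated BALF proteins and predicts from the in-silico bulk transcriptome:

```
selected 56 DLCO-linked features shared with the transcriptome vocabulary
mean predicted DLCO%  control: 78.9   ILD: 70.2
median predicted DLCO% by fibrosis stage:
stage
1    85.9
2    79.9
3    62.5
```

The model never sees transcriptome data during training; the lower ILD mean
and the monotone decline across fibrosis stages show that the protein-learned
lung-function signal transfers across modalities.  Detection-DE recovery
(`examples/01_simulate_and_detection_de.py`) prints, for a planted detection
shift of δ = 0.2 in AT2 cells:

```
planted disease genes recovered in the AT2 top-20 by |t|: 20/20
```

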