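# Methods

## The problem

Circulating extracellular-vesicle miRNAs are measured on single-color oligo
microarrays whose raw output is, per sample, a table of spot fluorescence
signals with scanner quality flags and probe-free BLANK spots. Two
preprocessing realities dominate downstream analysis of such data:

1. **Detection-limit missingness.** A spot whose signal does not clearly
   exceed the optical background cannot be distinguished from noise, so its
   value is set missing. Because this censors exactly the low-abundance
   end, the missingness is *missing not at random* (MNAR), and the choice of
   imputation strategy materially changes every later result.
2. **Batch effects.** Cohorts measured months apart differ systematically
   in location and spread on the log scale, which principal components pick
   up as the dominant axis of variation.

`mirpipe` implements the full space of 18 preprocessing pipelines that
combine six missing-value strategies, three normalizations and
empirical-Bayes batch correction in the orders in which they are used in
practice, plus the agreement metrics used to rank them — so the ranking
experiment can be rerun on any two-batch study, real or synthetic.

## Quality control

Per sample: (i) probe spots flagged `NG` become missing before any
arithmetic; (ii) background is the mean of BLANK-spot signals, with SD
estimated by the n−1 estimator (the spreadsheet/R convention; the vendor
convention is unspecified); (iii) two derived matrices are kept — the *BG
subtraction value* (signal − background mean, for all non-NG spots, possibly
negative) and the *converted value* (the same difference, kept only where
the signal strictly exceeds background mean + 2 SD). Ties at the threshold
are censored. miRNAs whose converted-value missing rate over all samples of
both batches strictly exceeds 0.95 are dropped from both matrices.

Background is computed per whole array; regional background estimation is a
scanner-software concern outside this package's scope.

## Missing-value strategies

| name | orientation | mechanism |
|---|---|---|
| constant | — | fill with 1 (maps to 0 after log2) |
| sample minimum | per column | fill with the sample's observed minimum |
| smallest-positive replacement | per column | negatives and missing → smallest positive observed (BG-subtraction variant) |
| kNN | miRNA rows | mean of the k=10 nearest rows' values; distance Euclidean over shared observed coordinates, normalized by coordinate count |
| EM | sample columns | multivariate-normal EM; fill with converged conditional means |
| iterative forest | sample columns | missForest-style: per-column random-forest regression, sweeps until the imputation-change criterion first rises |

Orientation matters: EM and the forest model the ~75 sample columns as
variables over ~2000 miRNA observations (the transpose would require
estimating a ~2000-dimensional covariance from 75 observations); kNN
instead neighbors miRNA rows, the gene-neighbor convention of expression
kNN imputation.

Numerical choices: the EM covariance carries a ridge term (default 1e−6) on
the diagonal and stops when the largest absolute parameter change drops
below 1e−4 (cap 100 iterations); rows are grouped by missingness pattern so
each conditional solve is done once per pattern. A `stochastic_draw` mode
replaces the conditional mean by one seeded draw from the conditional
normal, emulating a single random imputation (m = 1); the deterministic
conditional mean is the default because a single draw is not reproducible
across software without its seed. The forest uses 100 trees with
mtry = √p (the iterative-forest defaults), visits columns in ascending
missingness order, and returns the previous sweep's values when the
normalized squared difference Σ(new−prev)²/Σnew² over imputed positions
first increases. kNN ties in the distance ranking break by row order, so
the imputation is fully deterministic.

## Normalizations

* **Global median scaling** (linear scale): each sample's observed values
  are multiplied by 25/median.
* **log2** (requires strictly positive observed entries; the error names
  the offending cell).
* **75th-percentile subtraction** (log2 scale): the linear-interpolation
  quantile convention, so the observed 75th percentile is exactly 0
  afterwards; idempotent.
* **Quantile normalization**: with complete data, the classic rank-mean
  scheme with ties receiving the mean reference value of their tied span.
  With missing data (pipelines that normalize before imputing), each
  observed value maps through its column's empirical quantile
  (rank/(n−1)) onto the reference quantile function obtained by averaging
  the per-column quantile functions; masked entries stay masked. This
  reduces exactly to the rank-mean scheme when data are complete.

All statistics are computed over observed entries only; no transform ever
modifies the mask.

## Batch correction

Parametric empirical-Bayes location/scale correction with batch as the only
factor (no covariates), following the reference algorithm's conventions:
batch-size-weighted grand mean; pooled variance with a 1/n denominator;
per-batch standardized means (γ̂) and variances (δ̂, n−1); normal and
inverse-gamma priors with method-of-moments hyperparameters; fixed-point
iteration of the posterior equations to a relative tolerance of 1e−4 (cap
100, warning on non-convergence). Agreement with the Bioconductor reference
implementation is verified in the test suite to 1e−3 (the residual is
iteration stopping). A single-batch input has no batch contrast, so it is
returned unchanged with γ* = 0, δ* = 1; degenerate priors (zero variance of
γ̂ or δ̂ across miRNAs) disable shrinkage for that parameter rather than
dividing by zero.

Shrinkage makes removal of a true additive shift approximate: with a +2
shift, noise SD 0.6 and batches of 28/47, the per-miRNA between-batch
residual after correction has an irreducible mean magnitude of ~0.11
(estimation noise of γ̂ times one minus the shrinkage weight), centered on
zero; the package's tests assert the centering and that >90% of the shift
magnitude is removed, and the PCA significance pattern before/after
correction.

## The 18 pipelines

Declarative stage lists over one of the two QC matrices, always ending in
batch correction, with snapshots at three checkpoints: after imputation
(1), after the last pre-correction stage (2), after correction (3).
Pipelines 5/6 run on the BG-subtraction matrix with the smallest-positive
replacement; all others use the converted matrix. Pipelines 3/4 run the
forest imputation directly on the converted values (no prior global median
scaling; a `p34_global_median` switch restores the other reading of the
step list, which is ambiguous). Pipelines 13/14 and 17/18 use the order
log2 → impute → normalize → correct, the only self-consistent reading of
their step lists. Per-pipeline and per-stage seeds are derived from the
master seed through `numpy` seed sequences, so any subset of pipelines
reproduces bit-identically regardless of which other pipelines run.

## Evaluation

Agreement between batches is computed over the common sample pairs, on
(pair, miRNA) units pooled into one two-way layout — units as ANOVA
subjects, the two batches as raters:

    ICC(2,1) = (MS_C − MS_E) / (MS_C + MS_E + (2/N)(MS_B − MS_E))

with the 95% interval from the two-way-random absolute-agreement
single-measure construction and a test of H0: ICC = 0 via F = MS_C/MS_E on
(N−1, N−1) df. RMSE is the root mean squared between-batch difference over
the units; NRMSE divides by the range of the batch-1 values. Units are
split by pre-imputation NA rate: 0.5 (missing in exactly one batch — the
imputation-accuracy set) and 0 (measured in both — the
preprocessing-influence set); units missing in both batches belong to
neither. Snapshots still on the linear scale (checkpoint 1 of pipelines
1–6) are log2-transformed before agreement metrics, which are defined on
log-normalized values.

Batch effects are scored by Welch t-tests (the conservative default; the
equal-variance variant is not assumed) comparing batch-1 vs batch-2 scores
on the first two principal components of the common-sample columns, with
per-miRNA centering and no variance scaling (the expression-matrix PCA
convention). A zero-variance contrast yields p = 1 rather than NaN.
Benjamini–Hochberg adjustment is applied within metric families: PC
p-values jointly across pipelines × components × checkpoints; ICC p-values
across pipelines within each (checkpoint, NA-rate) family.

## The synthetic generator

Per miRNA j and sample entity e, the latent noise-free log2 abundance is
a_j + s_e with a_j ~ N(3.7, 4²) and s_e ~ N(0, 0.5²); common samples of the
two batches share one entity. Per-spot log2 signals add the batch-2
location shift (default 2), per-spot Gaussian noise (SD 0.6; ×1.5 in batch
2), and the raw fluorescence is background level (100) plus 2^signal, so
the detection rule operates on the same raw scale as real data. BLANK spots
draw from N(100, 20²); `NG` flags are assigned independently of signal at
rate 0.01 (no flag mechanism is modeled; MNAR comes solely from the
detection limit). Defaults are desk scale: 300 miRNAs, 12 blanks, batches
of 28 and 47 sharing 10 common samples.

The abundance and noise defaults were calibrated once so that, per common
pair, the fraction of miRNAs missing in exactly one batch is ~0.19 and
observed in both ~0.33 (fractions of all probes) — the regime the package
is meant to exercise; the location/scale form of the batch effect is
exactly the family the empirical-Bayes correction models, making the
correction tests positive controls.

What the generator does *not* emulate: probe cross-hybridization, spatial
artifacts, dye effects, heavy-tailed or multimodal abundance distributions,
and miRNA–miRNA correlation beyond the shared sample factor. The last point
matters for interpreting imputer rankings: because the latent model is
jointly Gaussian, the EM imputer is model-matched and attains near-optimal
error *against the latent truth*, slightly ahead of the forest at the
imputation stage. The operational ranking — between-batch agreement of
imputed vs measured values at checkpoint 3 — nevertheless robustly orders
forest < EM < constant, the pattern real studies report; passing tests
demonstrate that pattern, not a universal superiority of any imputer on
real data.

## Problem sizes and budgets

The package's own checks run at desk scale (300 miRNAs; ~200 retained after
QC) for end-to-end properties, 200 miRNAs × 10 seeds for the
imputer-ordering check (the smallest size at which the forest has enough
rows to learn the cross-sample structure), and 20 seeds for the
batch-correction significance pattern. The full-platform scale (2632
miRNAs) remains a configuration choice and changes runtimes roughly
linearly in the miRNA count.

## Known limitations

* Only the parametric EB variant of batch correction; no reference-batch,
  mean-only, or count-data variants, and no covariate preservation.
* Multiple imputation with m > 1 and pooling is not implemented.
* The kNN imputer honors the documented k and max-missing parameters but
  not the recursive two-means fallback some implementations use for very
  large matrices.
* Differential-expression evaluation is out of scope; the metrics judge
  agreement and batch-effect suppression only.
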