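# mirpipe

Benchmarking preprocessing pipelines for two-batch extracellular-vesicle
miRNA microarray data.

Single-color miRNA arrays (3D-Gene-style) report per-spot fluorescence with
scanner flags and probe-free BLANK spots. Signals that do not clearly exceed
the optical background are censored, so missingness concentrates at low
abundance (MNAR), and cohorts measured separately carry location/scale batch
effects. How you impute, normalize and batch-correct — and in which order —
changes every downstream result. `mirpipe` implements the 18 pipeline
orderings that combine:

* six missing-value strategies — constant-1, iterative random forest
  (missForest-style), smallest-positive replacement, per-sample minimum,
  k-nearest-neighbor rows, multivariate-normal EM;
* three normalizations — global median-to-25 scaling, 75th-percentile
  subtraction, quantile normalization (all missingness-aware), plus log2;
* parametric empirical-Bayes batch correction (ComBat);

and the evaluation layer used to rank them on the samples common to both
batches: the pooled two-way random-effects intraclass correlation

    ICC(2,1) = (MS_C − MS_E) / (MS_C + MS_E + (2/N)(MS_B − MS_E)),

RMSE/NRMSE between batches, and Welch t-tests on PC1/PC2 scores with
Benjamini–Hochberg adjustment. (Pair, miRNA) units are split by
pre-imputation NA rate: 0.5 = missing in exactly one batch (imputation
accuracy), 0 = measured in both (preprocessing influence).

A seeded synthetic-study generator with latent ground truth (two batches of
28 and 47 samples sharing 10, detection-limit MNAR, location/scale batch
effect) makes the whole benchmark reproducible without any external data.
See `docs/methods.md` for the model and all numerical conventions.

## Worked example

```
mirpipe simulate --seed 7 --out study/
mirpipe qc --study study/ --out mats/
mirpipe run --matrices mats/ --study study/ --pipelines 1,9,15 --seed 7 --out runs/
mirpipe evaluate --study study/ --runs runs/ --out report/
mirpipe report --report report/
```

which prints (seed 7):

```
               icc         nrmse
na_rate        0.0    0.5    0.0    0.5
pipeline_id
1            0.787  0.001  0.111  0.143
9            0.823  0.660  0.105  0.082
15           0.831  0.569  0.110  0.098
```

Reading: on miRNAs measured in both batches (NA rate 0) all three pipelines
preserve agreement about equally (ICC ≈ 0.8). On miRNAs imputed in one
batch (NA rate 0.5) the constant-1 pipeline (1) collapses to ICC ≈ 0, while
the forest pipeline (9, ICC 0.66) and the EM pipeline (15, ICC 0.57) keep
most of it — imputation quality, not normalization, dominates between-batch
agreement, and the forest leads.

The same objects are available as a library:

```python
import mirpipe as mp

study = mp.generate_two_batch_study(mp.GeneratorConfig(seed=7))
converted, bg = mp.qc_arrays(study.arrays, study.batch_of)
runs = mp.run_all(mp.builtin_pipelines(), converted, bg, seed=7)
report = mp.evaluate_study(runs, study.common_pairs)
print(report.agreement.head())
```

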