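# entroscan

Optimized multiscale entropy analysis of regional brain time series: objective
selection of the entropy parameters by ROC/AUC, biomarker-region discovery,
and classification with a probabilistic neural network.

## The problem

Sample entropy (SampEn) and its multiscale extension (MSE) quantify the
temporal irregularity of physiological signals such as resting-state fMRI
BOLD time courses.  Under the *complexity loss* hypothesis, aging and
impairment reduce signal complexity, so regional entropy can separate groups
that differ in cognitive performance.  MSE, however, has three free
parameters — embedding dimension *m*, similarity factor *r*, and scale
factor *τ* — that are traditionally chosen by convention or experience.
`entroscan` implements an objective alternative: the parameters are chosen
to maximize the between-group discriminability of regional entropy, measured
by significance counts and the area under the ROC curve.

## The model

For a series of length *N*, coarse-graining at scale *τ* replaces
non-overlapping blocks of *τ* samples by their mean,

&nbsp;&nbsp;&nbsp;&nbsp;*y*⁽*τ*⁾ⱼ = (1/τ) Σᵢ₌₍ⱼ₋₁₎τ₊₁^{jτ} *x*ᵢ ,  *L* = ⌊N/τ⌋,

and sample entropy of the coarse series is

&nbsp;&nbsp;&nbsp;&nbsp;SampEn(*m*, *r*) = −ln ( *A* / *B* ),

where *B* counts pairs of *m*-point templates whose Chebyshev distance is
strictly below *r*, *A* counts the same pairs at dimension *m*+1, and
self-matches are excluded.  Each regional series is z-scored once at scale 1,
so *r* is in SD units.  The pipeline then:

1. computes, for every (*m*, *r*, *τ*, region) grid cell, a two-sample Welch
   t-test and the ROC/AUC of the per-subject entropies between the two groups
   (defaults: *m* ∈ {1, 2}, *r* = 0.05–0.60 step 0.05, *τ* = 1–6, α = 0.05);
2. picks *m* by the mean count of significant regions, the robust *r* band
   (significant at every *τ*), and then (*τ*\*, *r*\*) by maximal mean AUC over
   significant regions;
3. declares the regions significant at the optimum to be biomarkers and
   builds per-subject entropy feature vectors over them;
4. classifies subjects with a Parzen-window probabilistic neural network
   (Gaussian kernels, class-normalized sums, no weight training), tuning the
   smoothing factor σ on a 0.1–2.0 grid, and reports stratified 10-fold
   cross-validated accuracy.

A synthetic-cohort generator produces two-group region × time datasets in
which a chosen subset of regions is more regular (AR(1) with a larger
autoregressive coefficient) in the poor group, so the whole pipeline is
testable without any external data.

## Worked example

Generate a small planted cohort (12 + 12 subjects, 20 regions, 3 of them —
indices 2, 7, 11 — with reduced complexity in the poor group), then run the
full pipeline:

```sh
$ entroscan synth --n0 12 --n1 12 --regions 20 --timepoints 175 \
      --planted 2,7,11 --seed 23 --out demo/cohort
wrote cohort to demo/cohort

$ entroscan run --manifest demo/cohort/manifest.csv --seed 23 --out demo/results
optimal m=1 r=0.35 tau=1; 3 biomarkers; sigma=0.1; CV mean accuracy 100.00%
```

The run selected *m* = 1 (more significant regions than *m* = 2), tolerance
*r* = 0.35 and scale *τ* = 1 (the cell with the highest mean AUC over
significant regions), and recovered exactly the three planted regions as
biomarkers (`demo/results/biomarkers.tsv`, ascending p):

```
region     p                       auc  t
ROI_008    3.4853346171521794e-11  1    -13.32369264661205
ROI_003    1.1158243855572016e-07  1    -9.473709629979945
ROI_012    1.1880237269637707e-07  1    -9.2359003282983174
```

The negative t statistics show the poor group's entropy is lower (complexity
loss direction), AUC = 1 means the per-subject entropies separate the groups
perfectly, and the PNN's cross-validated accuracy is 100% on this strongly
planted effect.  `demo/results/run_record.json` captures the full
configuration, selection trace, seeds and warnings needed to reproduce the
run.

The same stages are available as a library — `run_grid`, `select_m`,
`robust_r_band`, `select_tau_r`, `select_biomarkers`, `build_features`,
`PNNClassifier`, `cross_validate` — plus estimator-style wrappers
(`EntropyBiomarkerOptimizer`, `PNNClassifier`) that follow scikit-learn
conventions.

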