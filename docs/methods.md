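# Methods

This note records the scientific conventions, defaults and design choices
behind `entroscan`, in the spirit of the model documentation shipped with
packages such as statsmodels or msprime.

## Sample entropy and multiscale entropy

For a z-scored series *y* of length *L*, sample entropy is
SampEn(*m*, *r*) = −ln(*A*/*B*), with

* **templates** — *m*-point subsequences; both *B* (dimension *m*) and *A*
  (dimension *m*+1) run over the *L* − *m* templates that can be extended to
  *m*+1 points, so *A*/*B* is a proper conditional probability (the standard
  SampEn convention).  The literature contains variants that use
  *L* − *m* + 1 templates in the denominator; they disagree only through
  edge templates and the conditional-probability form is the one implemented
  and oracle-tested here.
* **matching** — Chebyshev (max-coordinate) distance, strict inequality
  *d* < *r*, self-matches excluded.  Matches are counted as unordered pairs;
  the ratio is identical to the ordered-count formulation.
* **tolerance units** — each regional series is z-scored once at scale 1
  (population SD) and *not* re-normalized after coarse-graining.  *r* is
  therefore in SD units of the original series, which preserves the
  cross-scale complexity-loss interpretation and makes the conventional
  *r* range 0.05–0.60 meaningful for any signal amplitude.
* **undefined values** — when either match count is zero, or the input has
  zero variance, the entropy is undefined and is marked NaN; `MSECurve`
  carries an explicit `undefined_mask`, batch tables carry a `defined` flag,
  and downstream statistics exclude flagged values while recording how many
  subjects were excluded per cell.  No ±∞ is ever produced.
* **series length** — a coarse series shorter than 10·*m* points triggers a
  UserWarning (not an error): roughly 10^m–20^m points are needed for a
  stable estimate, which is also why the default search caps *m* at 2 for
  175-point series.

Counting is exact integer arithmetic.  Two code paths exist: an O(L²)
pair-enumeration kernel (numba) used for all short series and all *m*, and
an O(L log L) sorted/Fenwick path for *m* = 1 on series longer than 4096
points (sliding window over the first template coordinate, orthogonal range
counting over the second).  Both implement the identical strict convention
and are cross-checked against each other and against a brute-force oracle in
the tests; the final −ln uses scalar `math.log` of the exact integer counts
so results are bit-reproducible across paths.

## Group statistics

* **significance** — two-sided Welch (unequal-variance) t-test per region.
  Welch is the default because group sizes are typically unbalanced and
  variance equality is unverified; an `equal_var` flag restores the pooled
  test.  p-values are uncorrected across regions by default, matching the
  original uncorrected procedure; Benjamini–Hochberg is available behind a
  flag on biomarker selection.
* **sensitivity** — AUC computed as the tie-corrected Mann–Whitney statistic
  U/(n₀·n₁) with group 1 ("excellent") as the positive class and higher
  entropy counting toward the positive class.  Below-chance values are
  reported as-is, never folded around 0.5, so the direction can be audited.
  The explicit ROC curve (score ≥ v thresholds, tied scores grouped) has
  trapezoidal area exactly equal to the U-statistic; this equality is a
  tested invariant.
* **AUC quality bands** — 0.50–0.59 poor, 0.60–0.69 bad, 0.70–0.79 medium,
  0.80–0.89 good, 0.90–1 excellent, half-open at the upper edge of each
  band; values below 0.50 map to "below-chance".

## Parameter selection

The search space defaults to *m* ∈ {1, 2}, *r* = 0.05–0.60 in steps of 0.05,
*τ* = 1–6, α = 0.05.  Selection is sequential, mirroring the order in which
the quantities constrain one another:

1. ***m*** — the dimension maximizing the mean significant-region count over
   all (*r*, *τ*) cells; ties break to the smaller *m* (shorter templates
   are better supported at a fixed series length).
2. **robust *r* band** — the *r* values keeping at least `min_regions`
   (default 1) regions significant at *every* *τ*.  An empty band falls
   back, with a warning, to the *r* with the best worst-case count over *τ*
   (ties: higher mean count, then smaller *r*).
3. **(*τ*\*, *r*\*)** — each cell in band × *τ* is scored by the mean AUC
   over its significant regions; *τ*\* maximizes the best in-band score
   (ties to the smaller *τ*, i.e. the finer scale), then *r*\* maximizes the
   score at *τ*\* (ties to the *r* nearest the band midpoint, then smaller).
   Scoring by mean AUC over significant regions formalizes the exemplar-
   region inspection used in practice while removing the subjective choice
   of exemplar; when a single region dominates, the two coincide.
4. **biomarkers** — regions with p < α at the optimum, ascending p.  An
   empty set is an error carrying the ten nearest misses for diagnosis.

The whole optimization is a pure function of (dataset, grids, α): reruns are
bit-identical, and the recorded selection trace replays to the same optimum.
A `joint_argmax` flag replaces step 3's sequential choice with a joint
argmax for sensitivity analysis.

## PNN classifier

A Parzen-window Bayes classifier: one Gaussian kernel
exp(−‖x − w‖²/2σ²) per stored training exemplar, per-class kernel sums
normalized by class size (uniform priors — the groups are unbalanced and
the sampling design, not the population, sets their ratio; a
`priors="proportional"` option restores frequency weighting), decision by
argmax with exact ties resolved to the lowest class label.  Scores are
computed in the log domain (log-sum-exp), so σ → 0⁺ degrades exactly to
nearest-exemplar classification and σ → ∞ to the tie limit; both limits are
tested numerically, as is invariance under duplicating every exemplar.

* **σ tuning** — grid 0.1–2.0 in steps of 0.1 (20 candidates), chosen by
  stratified cross-validated accuracy on the training features; ties break
  to the smaller σ.
* **validation** — stratified shuffled folds built deterministically from
  one explicit seed (each class dealt across folds, surplus to the
  least-loaded folds, so overall fold sizes differ by at most one);
  feature columns are z-scored with training-fold statistics only, so no
  information leaks from held-out subjects.  A paper-style stratified
  holdout (given test counts per class) is also provided.  Accuracies are
  reported in percent with mean and population SD, and every report records
  its seed and σ.

## Synthetic cohorts

The generator emulates the output of a two-group regional-BOLD study:
each region × time series is a stationary AR(1) process
x_t = φ x_{t−1} + ε_t with ε ~ N(0, noise_sd²), burn-in 500 samples
discarded.  Defaults — two groups of 30 subjects, 90 regions with AAL-90
labels, 175 time points, φ_base = 0.2, noise_sd = 1 — and in the nine
planted regions of group 0 (by default the nine biomarker AAL regions:
CAL.R, SFGmed.L, PCG.L, ITG.L, STG.R, CUN.R, PUT.R, HIP.R, TPOmid.R) the
coefficient is φ_base + Δφ with Δφ = 0.5, making those series more regular
and hence lower-entropy (the complexity-loss direction).  AR(1) was chosen
over fractional Gaussian noise as the complexity knob because a single
parameter with closed-form lag-1 autocorrelation (= φ) permits cheap,
exact validation; an fGn mode would be a natural extension.

What the generator does *not* emulate: hemodynamic response shapes, spatial
correlation between regions, scanner drift and realistic fMRI noise
spectra, or subject-level covariates.  Passing tests therefore demonstrate
that the pipeline recovers planted temporal-regularity differences under
idealized noise — not that any particular real cohort would yield the same
parameters or accuracy.

A property worth knowing when interpreting recovery tests: the planted
AR(1) contrast is strongest at scale 1 and *inverts* at coarse scales
(coarse-graining whitens the low-φ series faster than the high-φ ones — a
genuine multiscale crossover), so on these cohorts the optimizer selects
small *τ*.  Scale-localized effects at coarser scales would require a
different generative knob.

## Problem sizes and numerical choices

* Tests and the acceptance script run cohorts at the default study scale
  (60 subjects × 90 regions × 175 points; a full grid is 12,960 cells) and
  20-seed replicates for recovery checks; the analytic white-noise check
  uses a single 10⁵-point series, where the estimate matches
  −ln erf(r/2) to within 0.002.
* Grid r values are rounded to the grid (two decimals) so float equality
  against the grid is reliable; cell lookups use `np.isclose`.
* Matrices and tables are written with %.17g and read back with
  round-trip float parsing, so every artifact round-trips bit-identically.
* Degenerate inputs: zero-variance series → NaN entropy everywhere;
  all-undefined cells are recorded as exclusions, never dropped silently;
  subjects with any undefined feature are dropped from the feature matrix
  and listed by id.

## Known limitations

* Only two embedding dimensions are searched; longer series would justify
  m > 2 and a wider τ range.
* The t-test assumes approximate normality of per-region entropy values;
  with very small groups a permutation test would be preferable.
* Uncorrected per-region testing (the default, chosen for fidelity to the
  original procedure) implies an expected α·(n_regions − effects) false
  positives per run; enable the FDR flag when region-level inference
  matters.
* PNN accuracy is sensitive to feature scaling; the pipeline standardizes
  within folds, so σ values are comparable across datasets but not to
  unstandardized deployments.
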