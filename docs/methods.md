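# Methods

This note records the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of `nmqc`.

## 1. Normative model

### Likelihood and prior

For one imaging-derived phenotype (IDP) `y` observed at age `x`, the
model is Bayesian linear regression on a warped response:

```
t = phi(y)
t = Phi(x)' w + e,   e ~ N(0, 1/beta),   w ~ N(0, (1/alpha) I_M)
```

`Phi(x)` is a clamped cubic B-spline basis (order 4) with 5 evenly
spaced knots spanning the training age range, giving `M = 7` basis
functions that form a partition of unity. Prediction ages outside the
training domain are clamped to the boundary with a logged warning
(B-spline extrapolation is unbounded and was judged worse than a
constant boundary trend).

### Warp

`phi` is the sinh-arcsinh transform

```
phi(y)      = sinh( delta * asinh((y - a0)/b0) - epsilon )
phi^{-1}(t) = a0 + b0 * sinh( (asinh(t) + epsilon) / delta )
```

`a0, b0` are affine location/scale; `epsilon` controls skew and `delta`
tail weight. `delta = 1, epsilon = 0` recovers an affine (Gaussian)
model, so the Gaussian case is nested and testable. The log-derivative
needed for the likelihood Jacobian is computed with a numerically
stable `log cosh(x) = |x| + log1p(exp(-2|x|)) - log 2`.

### Marginal-likelihood fit

With the weights integrated out analytically, the negative log marginal
likelihood of `theta = (log alpha, log beta, epsilon, log delta, a0, log b0)` is

```
NLL = 1/2 [ n log 2*pi - n log beta - M log alpha + log|A|
            + beta ||t - Phi m||^2 + alpha ||m||^2 ]  -  sum_i log phi'(y_i)
A   = alpha I + beta Phi' Phi,     m = beta A^{-1} Phi' t
```

minimised with L-BFGS-B under box bounds:
`log alpha, log beta in [-12, 12]`, `epsilon in [-3, 3]`,
`log delta in [log 0.2, log 5]`, `a0 in mean(y) +/- 5 sd(y)`,
`log b0 in log sd(y) +/- 4`. Three deterministic restarts (identity
warp start plus two seeded perturbations) guard against local optima;
the best NLL wins. Optimiser tolerance is `ftol = 1e-9` with
`maxiter = 500`: L-BFGS-B's `ftol` is *relative*, and a looser value
was observed to stop before the warp parameters had converged even
though the objective looked flat. Linear algebra uses Cholesky
factorisation of `A`; any numerical failure inside the objective
returns a large finite penalty instead of propagating NaN.

### Scores, centiles, fit statistics

The z-score is computed on the warped scale,

```
z = (phi(y) - Phi' m) / sqrt( 1/beta + Phi' A^{-1} Phi )
```

i.e. residual over the predictive SD including both noise and
weight-posterior uncertainty. Centile `q` at age `x` is the inverse
warp of the latent Gaussian quantile,
`phi^{-1}( Phi' m + z_q * sqrt(sigma^2 + sigma_*^2) )`; the median is
the inverse-warped latent mean and is used as the point prediction
`y_hat`. Explained variance is reported on the original scale with
`y_hat`; skew and excess kurtosis are Fisher moments of the held-out
z-scores — for a well-specified model both should be near 0. A refit
comparison utility refits the model with flagged subjects removed and
reports a paired t-test on per-subject absolute errors, to check that
outlier removal does not materially change the normative surface.

## 2. Outlier rule

A subject is flagged for an IDP when `|z| > 7` (strict, two-sided).
Under a calibrated N(0,1) null the two-sided tail mass at 7 SD is
~2.6e-12, so any flag in realistic cohort sizes is effectively
impossible by chance; this buys specificity at the cost of missing
moderate artefacts, which is the intended operating point for
automated exclusion. Frequencies are reported per subject and per IDP,
flagged subjects can carry review categories
(acquisition / processing / incidental / unreviewed), and flag sets are
nested in the threshold by construction.

## 3. Synthetic cohort generator

The generator exists to validate the QC chain against known truth; it
is deliberately simple and tabular.

- 24 IDPs: {FA, MD, ICVF, ISOVF} x 6 white-matter tracts. Each IDP has
  a latent age trend (7 B-spline control values encoding a smooth,
  mostly monotone trajectory with tract-specific curvature), unit
  Gaussian latent noise, and a metric-specific sinh-arcsinh warp to the
  observed scale (e.g. FA ≈ 0.45 ± 0.035 with negative skew). Ages are
  uniform on [45, 85].
- Artefacts: each subject belongs to at most one contamination class.
  A class has a category, a prevalence (restricted to [0, 0.1) — the
  rare-event regime the rule targets), a set of affected IDPs, a latent
  shift in residual SDs (default ±10), and a ground-truth severity
  score in {2, 3}. Defaults: acquisition artefacts (0.8 %) hitting all
  metrics in the corticospinal tracts, processing errors (0.6 %)
  hitting MD/ISOVF, incidental findings (0.3 %) hitting the corpus
  callosum.
- Raters: two simulated visual raters produce 1–3 scores from the true
  severity with adjacent-category confusion controlled by a
  reliability parameter (default 0.9).
- Conventional QC table: 21 Gaussian summary descriptors (SNR, motion,
  registration discrepancies, …) whose means shift per artefact
  category, emulating a conventional summary-metric QC tool.
- A `student-t` latent-noise mode provides a model-mismatch stress
  test.

The generator does **not** emulate images, spatial structure,
site/scanner effects, longitudinal repeats, or non-stationary noise;
conclusions about those must come from real data.

## 4. Comparison battery

- **ICC3k** (two-way mixed, consistency, average of k raters) from the
  ANOVA decomposition `(MS_subjects - MS_error)/MS_subjects`;
  unit-tested against `pingouin` as an independent oracle.
- **Balanced SVM**: 20 random balanced subsamples (negatives
  down-sampled to the positive count) x stratified 5-fold CV of a
  linear SVM (standardised features) predicting severe (score 3) vs
  not (1–2); reports mean ± SD accuracy/sensitivity/specificity.
- **Precision–recall**: step-wise average precision
  (`sum_k P_k (R_k - R_{k-1})` over descending score cut-points, via
  scikit-learn) for (a) per-threshold outlier counts at |z| > 2…7 and
  (b) the continuous score `max |z|` per subject.
- **Conventional-QC rule**: flag any descriptor beyond 2 sample SDs of
  its column mean; zero-variance columns are dropped with a warning.
- **Correlation matrix** of six per-subject QC measures
  (two registration discrepancies, SNR, normative outlier count,
  conventional-QC outlier count, mean visual score), Pearson.

## 5. Clean-reference training (`train_on_clean`)

Maximum-likelihood warp fitting is *not* robust to rare extreme
contamination in the training data. Empirically, with 10–40 SD shifted
subjects at prevalences of 0.1–2 % and training sizes up to 20 000,
the optimiser bends the tail parameters (`delta` to its lower bound,
or large `epsilon`) so that the contaminated points cost almost
nothing in bulk likelihood — and the contamination is then compressed
below the 7-SD line at scoring time. Tightening the bounds on
`delta`/`epsilon` does not fix this; it is a property of the flexible
tail, not of the optimiser.

Consequently, a trustworthy reference model requires curated (clean)
training data. The pipeline exposes `PipelineConfig.train_on_clean`,
which in synthetic studies trains only on ground-truth-clean subjects;
in real deployments the analogue is an initial visually-curated
reference cohort, after which the fitted models can score arbitrary new
data. With clean references, detection simulations reach sensitivity
1.0 at 10-SD shifts with zero false flags in ~10^5 clean cells.

## 6. Determinism and problem sizes

All stochastic steps take explicit integer seeds; derived seeds are
drawn below 2^31. The full pipeline writes byte-identical artifacts
across repeated runs (manifest included; no timestamps). Default study
sizes (cohorts of 2 000–10 000 subjects, 24 IDPs) were chosen so that
the entire test suite and the acceptance script each run in minutes on
one CPU while keeping Monte-Carlo error well inside the test
tolerances.

## 7. Limitations

- Single covariate (age). Sex is generated but not modelled; adding
  covariates only requires widening the design matrix.
- The warp fixes one global shape per IDP; age-dependent
  skew/heteroscedasticity beyond what the B-spline mean absorbs is not
  modelled.
- The 7-SD rule targets gross artefacts only; subtle artefacts
  (few-SD shifts) are intentionally outside its operating point.
- ML warp fitting is non-robust to training contamination (see §5);
  `train_on_clean` mitigates this in simulation but real deployments
  need a curated reference.
- The synthetic generator is tabular and omits spatial, site and
  longitudinal structure.
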