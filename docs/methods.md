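# Methods

This note documents the statistical model behind `condsem`, the defaults and
numerical choices, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Model and estimation

`condsem` fits linear covariance-structure models in the RAM (reticular
action model) form.  The full variable vector `v` of length `t` stacks all
observed, latent and composite variables; the model is

    v = A v + u,      u ~ N(0, S),

where `A` collects every directed coefficient (factor loadings λ, regression
slopes, composite weights γ) and `S` every variance and covariance (residual
variances ε, exogenous variances/covariances, correlated errors).  Because
the directed part of the graph is required to be acyclic, `(I − A)` is always
invertible and the implied covariance of the `p` observed variables is
`Σ(θ) = F (I − A)⁻¹ S (I − A)⁻ᵀ Fᵀ` with `F` the observed-row selector.

Estimation minimizes the classical Wishart maximum-likelihood discrepancy on
the (N−1)-denominator sample covariance,

    F_ML(S, Σ) = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p,

summed over groups with weights `(N_g − 1)/(N − G)`; the model chi-square is
`T = Σ_g (N_g − 1) F_g`.  A flag (`fit_ml(..., n_scaling="n")`) switches to
plain-N scaling; the two differ negligibly at the sample sizes this package
targets (hundreds of rows) but the convention is explicit rather than
implicit.  Missing data are handled by listwise deletion with the retained N
logged and recorded; full-information ML is deliberately out of scope.

**Composites.** A composite is a latent variable whose residual variance is
pinned to exactly 0, so it is fully determined by its causes:
`C = Σ γ_i X_i`.  An *unknown-weight* composite needs an outcome to be
estimable; anchored on survival, its weights are exactly the multiple-
regression solution, which the test suite verifies against ordinary least
squares to 1e-6.  A regression **into** a composite (the density term of the
condition model) enters the structural matrix like any slope but is *not*
part of the index definition: factor scores for a composite are the weighted
sum of its `<~` causes only, so the index remains a function of the measured
condition variables alone.

**MIMIC blocks.** Confounder correction uses multiple-indicator
multiple-cause structures: covariates regress on a latent that carries a
single indicator with loading fixed to 1.  A standalone single-indicator
MIMIC block cannot separate the latent residual from the indicator residual,
so the builders pin the indicator residual to 0; the latent then coincides
with the observed variable while its covariates are partialled out inside
the joint model — the in-model equivalent of "residual mass", without the
two-step residual analysis.  `apply_identification` itself leaves the
indicator residual free, because in richer models (two indicators, or
downstream paths) the split can be identified and should not be silently
destroyed.

**Identification defaults.** Latents are scaled by fixing their first listed
loading to 1 (`std_lv=True` fixes the latent variance instead); composites
by fixing their first cause weight to 1 unless the user fixed another weight
or an outgoing path.  Every variable receives a variance term; exogenous
observed variables (and exogenous latents) covary freely unless a covariance
is explicitly fixed.  Intercepts are excluded by default: every reported
quantity is a covariance-level path coefficient.  Enabling `meanstructure`
adds saturated observed intercepts (and the mean term of the discrepancy),
which leaves the df unchanged but makes implied means available.

**Standard errors and standardization.** Wald standard errors come from the
inverse numerical Hessian (central differences of the analytic gradient) of
the `T/2`-scaled objective, with two-sided normal p-values and no
multiple-testing correction.  Standardized coefficients are
`b · sd(predictor)/sd(response)` with model-implied standard deviations from
the full `t × t` implied covariance; covariances become correlations and
variances become proportions of implied variance, so a scale-set exogenous
latent standardizes to variance 1.  Standardized estimates are invariant to
rescaling any observed column (tested to 1e-6).

**Fit indices and model comparison.** The baseline for the comparative fit
index is the independence model (free variances, zero covariances), whose ML
solution is closed-form: per group `F_b = −ln|R|` with `R` the sample
correlation matrix, `df_b = p(p−1)/2`.  CFI is clipped to [0, 1] and
reported as 1 (with a warning) when the baseline chi-square does not exceed
its df.  Nested models are compared by the chi-square difference referenced
to `Δdf`; the test refuses equal-df pairs and models fitted to different
moments, and warns when the difference is negative beyond tolerance (a
convergence problem, not a statistic).

## Numerical choices

* **Optimizer:** L-BFGS-B with the analytic gradient of the discrepancy
  (O(t³) per evaluation via the RAM trace identities).  Variance parameters
  are bounded below at 1e-10 rather than log-parameterized, so boundary
  (Heywood) solutions are visible in the parameter table instead of being
  pushed to −∞ on a log scale.
* **Internal standardization:** fitting happens on moments rescaled to
  pooled unit variance (the ML discrepancy is invariant to diagonal
  rescaling) and estimates are mapped back afterwards.  This keeps the
  optimization landscape conditioned regardless of measurement units — a
  gram/kilogram change of one column must not change any conclusion.  When
  an equality-constrained (labelled) parameter spans slots with different
  scale factors the rescaling is skipped to preserve the constraint.
* **Start values:** loadings and composite weights start at 1, regressions
  at 0, observed residual variances at half the sample variance, latent
  variances at half the variance of their scale-setting indicator, and
  exogenous observed (co)variances at their sample values — all computed on
  the standardized scale.
* **Convergence:** the fit is declared converged when the optimizer reports
  success or the gradient max-norm falls below 1e-5 on the O(1)-scaled
  objective (at most 10,000 iterations).  Non-converged fits carry their
  gradient norm and refuse standard errors, standardization and scoring.
* **Degenerate inputs:** non-positive-definite sample or implied covariances
  raise immediately with the offending construction named; a singular
  information matrix yields per-parameter NA standard errors with a warning
  rather than a failure; fitting is fully deterministic given data and
  model — there is no randomness anywhere in the estimation path.

## The synthetic-data generator

`simulate_dataset` draws multivariate-normal rows from the model-implied
covariance of a `TrueModel` (a spec plus a stated value for every free
parameter), deterministically per `(seed, stream)`; one seed fans out to
per-replicate substreams so each dataset of a simulation study is
individually reproducible.  The packaged fixtures emulate the structure of
the shorebird case study:

* `energy` — two energy-stores measures (mass, mass/tarsus ratio) with an
  implied correlation near 0.9, loading on one latent with three correlated
  structural-size covariates (pairwise r = 0.5).
* `colour_grouped` — hue/chroma/luminance on one colour factor whose
  intercorrelation is strong in adults (|r| ≈ 0.7–0.8) and weak in
  sub-adults (r ≈ 0.2), fitted as a multi-group CFA.
* `condition` — the composite condition index: six causes of which two are
  dominant (size-corrected mass, total effect on survival +0.40;
  corticosterone, −0.30) and four near zero (+0.02 to +0.04), competitor
  density depressing the index (−0.40) and the index raising survival
  (γ = 0.40).  Corticosterone correlates with structural size (r = 0.3) and
  the mass residual correlates with the physiological variables and density,
  which is precisely the confounding that biases the stepwise estimator
  while leaving the jointly-estimated SEM consistent.
* `full` — the complete confounder-corrected structure: the energy latent,
  hue, and five physiological variables each carrying a MIMIC correction
  (handling time, sex, age class; bill-tip height and sex for hue), the
  haematocrit–cholesterol error covariance, and the composite → survival and
  density → composite paths (about 90 free parameters, df = 76).

All fixture values are arbitrary but fixed in `condsem/simulate.py` as the
single source of truth.  The generator is Gaussian-only and simulates
survival directly as a continuous area-level variable.  It therefore does
**not** emulate: non-normal or bounded indicators (proportions, counts),
the shared-value structure of site-level survival attached to individual
birds (which understates standard errors in real data exactly as it does in
the case study), capture–mark–recapture uncertainty in the survival
estimates, or missing-data patterns.  Passing tests show the estimators are
correct under the stated Gaussian conditions — not that any particular field
dataset satisfies them.

## Evaluation harness

`run_bias_experiment` compares, per simulated dataset, the SEM total effects
`γ̂ · ŵ_i` of each condition variable on survival with the stepwise step-2
slopes, against the same generating truth.  It reports the mean bias and the
empirical standard error with the (nsim − 1) denominator, plus the relative
bias `100 · B̂/θ`, suppressed when `|θ| < 0.05` (configurable) because a
relative scale is meaningless near zero.  Replicates with non-converged SEM
fits are excluded and counted; more than 10% aborts the run.

`cross_validate` defaults to 10-fold partitions repeated 3 times — 30
distinct training/test sets, the only internally consistent reading of a
"10-fold, 80/20, three repeats" design (10-fold implies 90/10 splits); a
Monte-Carlo `mode="split"` with a configurable held-out fraction covers the
80/20 reading.  The SEM predicts test-set survival from the training-fit
composite weights and the condition → survival slope, anchored on the
training survival mean; the conventional method applies the training step-1
coefficients to form test residual mass and then the step-2 linear
predictor.  RMSE and R² = 1 − SSE/SST are computed on the pooled out-of-fold
predictions (R² may be negative); density is excluded from both models here
because the target is pure survival prediction.

## Problem sizes

The test suite and `scripts/acceptance.py` use scaled study sizes chosen to
keep Monte-Carlo error well below the margins being asserted: recovery fits
at n = 10,000; the bias experiment at 200 replicates of n = 1,000; the
type-I-error calibration at 500 replicates of n = 500; cross-validation on
n = 800 (and n = 2,000 for the null-response check).  At these sizes the
SEM's maximum flagged relative bias is well under 5% while the stepwise
estimator's exceeds 30% on the dominant variables, and the nested-model test
rejects at 4–6%.

## Known limitations

* No robust/sandwich or bootstrap standard errors; no FIML for missing data;
  no ordinal/threshold estimators; no random effects or multilevel
  structure.
* Composite weights are identified only up to the scale convention (first
  weight fixed); comparisons across methods therefore use total effects
  `γ · w_i`, which are scale-free.
* The full model's confounder → condition-variable edge set is only partly
  determined by the study design; it is exposed as configuration
  (`confounder_edges`) rather than hard-coded, and the packaged default is
  one defensible choice among several.
* Area-level survival is treated as an ordinary individual-level response;
  with shared values within sites the reported standard errors are
  optimistic, in the simulated data exactly as in the original analysis.
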