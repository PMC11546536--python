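# Methods

This note records the statistical model the package implements, the
numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and known limitations.

## Model and identification

Subjects contribute `O = (Y, X, A, D)` with `D = 1` for the randomized
trial, `D = 0` for external controls (always untreated). The target is the
average treatment effect in the study population,
`tau = E[Y^1 − Y^0 | D = 1]`. Working assumptions:

* **A1 consistency** — `Y = Y^a` when `A = a`;
* **A2 randomization within the trial** — `Y^a ⊥ A | D = 1`;
* **A3 treatment positivity** — the design randomization probability
  `pi_a = Pr(A=1|X, D=1)` lies strictly in (0, 1) and is known;
* **A4 mean exchangeability across sources** — for some measured
  `X`: `E[Y^0|X, D=1] = E[Y^0|X, D=0]`.

Under A1–A4, `tau = E[Y|A=1] − E_{X|D=1}[E(Y|A=0,X)]`. A4 is the
assumption that is *bought*, not guaranteed by design; the `swig` module
expresses it graphically (selection nodes on covariates whose conditional
law differs across populations; A4 holds given `X` iff the counterfactual
outcome is d-separated from all selection nodes given `X` in the
treatment-split graph), and the `diagnostics` module probes its testable
implication and propagates hypothesized violations.

Declarations of *which* conditionals differ across populations are user
inputs: they concern unknowable population quantities, so the package
treats them as explicit modelling assertions, with "declare every
covariate" as the conservative default in the CLI.

## Estimators

With `m_a(x) = E[Y|A=a, X=x]`, `pi_d(x) = Pr(D=1|X=x)`,
`q_hat = n_rct/n`, and `r` the internal:external control outcome variance
ratio:

* **om** — `mu0_om = n_rct^{-1} Σ D_i m0_hat(X_i)`; `tau_om = mean(Y|A=1) − mu0_om`.
* **ipdw** — weights
  `W_i = (1−A_i) pi_d_hat(X_i) / {[1−pi_a(X_i)] pi_d_hat(X_i) + [1−pi_d_hat(X_i)]}`;
  `mu0_ipdw = n_rct^{-1} Σ W_i Y_i` (a normalized/Hájek variant divides by
  `Σ W_i`; only the Hájek form is exactly invariant to shifting all
  outcomes by a constant).
* **aipw** — the sample mean of the uncentered efficient influence
  contribution (see README for the formula); solves the influence-curve
  estimating equation exactly, hence the stored influence values average
  to zero to machine precision.
* **tmle** — outcomes and initial fits are affinely mapped to [0, 1] using
  `L = min(Y) − δ`, `U = max(Y) + δ` (δ = 0 by default), a one-parameter
  logistic regression of the scaled outcome on the clever covariate
  `h(D, A, X)` with offset `logit(scaled m_A_hat)` is fit by IRLS on all n
  subjects, and the plug-in `n_rct^{-1} Σ D_i [m1*(X_i) − m0*(X_i)]` is
  taken after back-transforming. A single fluctuation solves the influence
  equation (the fitted score is exactly the residual influence term), so
  no iteration is performed; predictions are bounded in `[L, U]` by
  construction.
* **rct** — the trial-only covariate-adjusted AIPW comparator, computed by
  the same machinery on the `D = 1` subset with `pi_d ≡ 1` (no truncation)
  and `r ≡ 1`, which reduces algebraically to the standard within-trial
  AIPW estimator.

Both control-side weight expressions carry the factor `(1−A)` on the
external-control summand as well as the internal one; on valid data the
two conventions coincide (`D = 0` forces `A = 0`), and this choice keeps
the weight and the clever covariate algebraically consistent.

**Inference.** For aipw/tmle: `se = sd(phi_hat)/sqrt(n)` and
`tau_hat ± z_{1−alpha/2} se`, with the z-quantile computed from alpha
(1.959964 at 0.05). For om/ipdw: stratified nonparametric percentile
bootstrap — resampling with replacement independently within sources,
preserving `n_rct`/`n_ec`, refitting nuisances per resample (B = 1000 by
default); the p-value is the interval-inversion value
`2·min(tail fractions)` with +1 smoothing. Resamples lacking a required
stratum are redrawn and logged.

## Nuisance estimation

* Learners: `linear` (OLS), `logistic` (unpenalized MLE), `random_forest`,
  or any user-supplied scikit-learn estimator. `m1` is fit on treated
  subjects; `m0` on the pooled internal + external controls; `pi_d` on all
  subjects; `pi_a` is the design constant.
* **Cross-fitting** (default 10 folds): fold assignment is a seeded random
  partition stratified by `(A, D)` so every training split contains
  treated, internal-control and external-control units; all stored
  subject-level predictions are out-of-fold. Cross-fitting is what
  licenses data-adaptive nuisances while retaining root-n normal
  inference.
* **Truncation**: propensity predictions are clipped to
  `[0.01, 0.99]` (`trunc_eps` configurable). The identification theory
  assumes positivity; truncation is a variance-stabilizing device, and
  truncation events are visible in the stored predictions.
* **Variance ratio r**: modelled as a constant. Default `constant_one`
  (homoscedastic across sources — with `r = 1`, internal and external
  controls at the same `pi_d` receive identical weight). `pooled_ratio`
  estimates it as (mean squared residual of internal controls about
  `m0_hat`) / (same for external controls), floored at 1e-3. The
  orientation (internal variance in the numerator) is a package
  convention, recorded here because no standard convention pins it down;
  no covariate-varying model for `r` is offered.
* Random-forest defaults are deliberately modest — 20 trees,
  `min_samples_leaf = 5` — chosen once so that multi-hundred-replicate
  studies remain desk-scale; both are configurable via
  `LearnerSpec(m_params=..., pi_d_params=...)`.

## Diagnostics and sensitivity analysis

* `normalized_difference` — multivariate standardized mean difference
  between the internal and external control arms,
  `sqrt(2 d' (S1+S0)^{-1} d)`; affine invariant; pseudo-inverse with a
  warning when the pooled covariance is singular.
* `propensity_imbalance` — difference of mean estimated `pi_d` between
  sources; the conventional 0.25 threshold is attached as a *flag only*:
  no diagnostic is ever used as an automated gate, since imbalance does
  not by itself invalidate the estimators (and hypothesis tests on these
  summaries are deliberately not provided).
* `a4_bin_diagnostic` — controls bucketed by `pi_d_hat` in fixed-width
  bins (default 0.05); per bin × source: count, mean outcome, normal 95%
  CI (singleton cells report no CI rather than a t-interval).
* `estimate_bias_bound` — plug-in for the large-sample bias under a
  violation `u(X) = E[Y|A=0,D=1,X] − E[Y|A=0,D=0,X]`:
  separate control-outcome regressions per source give `u_hat`, a
  logistic model on controls gives `Pr(D=0|A=0,X)`, and the product is
  averaged over study subjects. The factored form
  `Pr(D=0|A=0) · mean(u_hat | D=1)` is reported alongside; the package
  reports both without claiming one dominates the other, because the
  ordering depends on the sign structure of `u`.
* `tipping_point` — for a constant violation `B`, the estimate shifts by
  `sign(tau)·Pr(D=0|A=0)·B`; the smallest `|B|` moving the CI to include
  zero is the near-zero CI endpoint divided by `Pr(D=0|A=0)` (closed form;
  0 if the CI already covers zero). The shifted interval keeps the
  original width — the analysis moves the location only.

## Synthetic-data generator

`simulate_trial` emulates the hybrid design studied throughout: exactly
150 trial subjects randomized 2:1 (`pi_a = 2/3`) and 50 external controls,
a continuous endpoint, and dependence between treatment and source through
a non-constant study propensity. Defaults, chosen once:

* Covariates: `x1, x2 ~ N(0,1)`, `x3, x4 ~ Bernoulli(1/2)` — a minimal mix
  of continuous and binary baseline factors.
* Study propensity: `pi_d(x) = expit(1.0 + 0.5 x1 − 0.3 x2 − 0.5 x1²)`
  (the quadratic term present only under "nonlinear truth"); source labels
  are drawn `D ~ Bernoulli(pi_d(x))` with rejection until both quotas are
  met, so realized counts are exact by design.
* Control outcome surface: `m0(x) = 1 + x1 + 0.5 x2 − 0.5 x3 + 0.5 x4`
  plus `0.7 x1² + 0.5 x1 x2` under nonlinear truth; `Y = m0(X) + tau·A + ε`,
  `ε ~ N(0, 1)`. The nonlinear terms are strong enough that linear analyst
  models are genuinely misspecified (singly robust bias ≈ 0.3–0.4 in the
  package's own studies) while remaining learnable by forests at n = 200.
* A4 holds by construction (identical `m0` in both sources); `u_shift`
  lowers external-control outcomes by a constant to inject a known
  violation for sensitivity-analysis testing; `tau_slope` optionally makes
  the effect heterogeneous in `x1` (the default is homogeneous so the true
  effect is design-known for coverage scoring).

Five `setting` tags bind truth to analyst learners (1: linear truth +
correct linear models; 2: nonlinear truth, misspecified linear `pi_d` +
forest outcome models; 3: misspecified linear outcome models + forest
`pi_d`; 4: both misspecified linear; 5: both forests). The singly robust
method whose nuisance is machine-learned in a setting is omitted from that
setting's report (no theoretically valid interval construction).

**What the generator does not emulate:** measured-covariate sets richer
than four variables, covariate measurement heterogeneity between sources,
non-Gaussian or heteroscedastic outcome noise, informative missingness
(the loader is complete-case by design), survival endpoints, and any
difference in outcome *definition* across sources. Passing simulation
tests therefore demonstrate the estimators' internal correctness and their
operating characteristics under this stylized design — not robustness to
every failure mode of real external-control data.

## Numerical choices and degenerate inputs

* TMLE scaling clips the scaled offset into `[1e-6, 1 − 1e-6]` before the
  logit; initial predictions outside the observed outcome range are
  thereby pulled to the range boundary (this is the bounding property, not
  an artifact). A degenerate outcome (`max Y = min Y`) is an error.
* The fluctuation is fit with IRLS (binomial quasi-likelihood, offset,
  single covariate, no intercept), tolerance 1e-12; non-convergence is an
  error carrying diagnostics rather than a silent fallback.
* Zero-variance influence vectors produce the degenerate interval
  `[tau_hat, tau_hat]` and are flagged.
* Fold counts must lie in `1..n`; strata emptied by resampling or
  subsetting raise errors naming the stratum.
* Replicate-level failures inside simulation studies are caught, counted,
  and excluded; a failure rate above 1% emits a warning.

## Replicate counts in the shipped studies

The acceptance script uses 1000 replicates for the linear-truth coverage
study and 500 for each forest study; the test suite uses 150–500 depending
on the check, with every acceptance band computed as a binomial
Monte-Carlo error band at the replicate count actually run. These sizes
are the package's own desk-scale choices; all are configurable.

## Known limitations

* Continuous outcomes only for TMLE (binary outcomes run through the
  same AIPW machinery, but no dedicated binary fluctuation is provided).
* `r` is constant, never covariate-varying.
* No weight truncation beyond propensity clipping, and no
  matching-on-`pi_d` alternative to weighting.
* The graphical module performs exhaustive enumeration for minimal
  adjustment sets (capped at 20 candidates).
* No Bayesian borrowing, no survival endpoints, no missing-data
  modelling.
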