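# hybridec

Doubly robust causal inference for **hybrid trials**: randomized controlled
trials whose analysis augments the internal control arm with **external
controls** (historical trial arms, registries, EHR cohorts). The motivating
use case is rare-disease trials — e.g. a motor-function trial in spinal
muscular atrophy — where a small pool of comparable historical placebo
patients can buy real precision, but only under an explicit exchangeability
assumption that deserves scrutiny rather than hope.

## The problem and the estimand

Observed data are `O = (Y, X, A, D)`: outcome, baseline covariates, binary
treatment, and source (`D = 1` trial, `D = 0` external control; external
controls are never treated). The estimand is the average treatment effect in
the study population,

    tau = E[Y^1 - Y^0 | D = 1],

which (because `D = 0` implies `A = 0` and treatment is randomized within the
trial) coincides with the effect among the treated. Randomization identifies
`E[Y^1 | D = 1]` as the treated-arm mean. Borrowing external controls for the
`Y^0` side requires **mean exchangeability across sources**: for some
measured covariate set `X`,

    E[Y^0 | X, D = 1] = E[Y^0 | X, D = 0].          (A4)

Then `tau = E[Y | A = 1] − E_{X|D=1}[ E(Y | A = 0, X) ]`.

`hybridec` provides:

* **Graphical assessment of A4** (`hybridec.swig`): build a *selection SWIG*
  — a causal DAG with the treatment node split (random/fixed halves) and
  selection nodes `S_Z → Z` marking covariates whose distribution differs
  between populations. A4 holds given `X` iff `Y^0` is d-separated from every
  `S` node given `X`.
* **Four estimators plus a trial-only comparator**
  (`hybridec.estimators`): outcome regression (g-computation), inverse
  probability of data-source weighting (IPDW), the augmented estimator
  (AIPW) built on the efficient influence curve

      phi(O) = (1/q) { D [m1(X) − m0(X) − tau]
                       + (DA / pi_a(X)) [Y − m1(X)]
                       − W_dr [Y − m0(X)] },

  with `W_dr = [D(1−A) pi_d + (1−D)(1−A) pi_d r] / [pi_d (1−pi_a) + (1−pi_d) r]`,
  and a targeted maximum likelihood estimator (TMLE) obtained by a
  one-parameter logistic fluctuation along the clever covariate
  `h(D,A,X) = (1/q){ DA/pi_a − W_dr }`. AIPW/TMLE are doubly robust
  (consistent if either the outcome models or the study propensity
  `pi_d(x) = Pr(D=1|X=x)` is consistent) and, with cross-fitting, attain the
  semiparametric efficiency bound even with machine-learned nuisances;
  closed-form CIs come from `tau_hat ± z * sd(phi_hat)/sqrt(n)`.
* **Cross-fitted nuisance models** (`hybridec.nuisance`): linear/logistic or
  random-forest learners, 10-fold cross-fitting stratified by arm and
  source, propensity truncation.
* **Diagnostics & sensitivity analysis** (`hybridec.diagnostics`):
  normalized covariate difference, study-propensity imbalance (flagged above
  0.25), a binned control-outcome comparison visualizing A4's testable
  implication, a plug-in estimate of the asymptotic bias
  `E[Pr(D=0|A=0,X) u(X) | D=1]` under violations `u(X)`, and the
  tipping-point magnitude `B` that would overturn significance.
* **A simulation engine** (`hybridec.simulate`) reproducing the design used
  throughout: 150 trial subjects randomized 2:1 plus 50 external controls,
  non-constant study propensity, linear or nonlinear outcome truth, and five
  truth/learner pairings for studying double robustness.

## Worked example

```python
import hybridec as h

# one synthetic hybrid trial: 150 RCT subjects (2:1), 50 external controls,
# true effect tau = 1
data = h.simulate_trial(h.setting_config(1, tau=1.0), seed=42)

fits = h.fit_nuisances(data, spec=h.LearnerSpec(), k_folds=10, seed=42)
for est in (h.estimate_tau_rct(data, fits),
            h.estimate_tau_aipw(data, fits),
            h.estimate_tau_tmle(data, fits)):
    print(f"{est.method:9s} tau_hat={est.tau_hat:5.3f}  "
          f"95% CI=({est.ci_low:5.3f}, {est.ci_high:5.3f})  p={est.p_value:.1e}")

print("propensity imbalance:", round(h.propensity_imbalance(data, fits), 3))
```

prints

```
rct_aipw  tau_hat=0.769  95% CI=(0.401, 1.136)  p=4.1e-05
aipw      tau_hat=0.969  95% CI=(0.669, 1.269)  p=2.4e-10
tmle      tau_hat=0.969  95% CI=(0.669, 1.268)  p=2.4e-10
propensity imbalance: 0.004
```

Both hybrid estimators recover the true effect (tau = 1) with a confidence
interval about 18% narrower than the trial-only analysis — the precision
gain that motivates borrowing — while the imbalance summary (0.004, well
under the 0.25 flag) says the two control pools are similar in this draw.

The same pipeline is available from the shell:

```bash
hybridec estimate --data trial.csv --method all --pi-a 0.6667 --out results/
hybridec swig-check --graph graph.txt --differs all --adjust Age,Type,Scoliosis,MFM0
hybridec simulate --setting 5 --reps 500 --out sim/
```

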