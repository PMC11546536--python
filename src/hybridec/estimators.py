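"""Estimators of the average treatment effect in the study population.

The target is tau = E[Y^1 - Y^0 | D = 1].  Under randomization within the
trial and mean exchangeability of the control potential outcome across
sources given X, tau = E[Y | A=1] - E_{X|D=1}[ E(Y | A=0, X) ], which the
module estimates five ways:

* ``om``   — g-computation: average m0-hat over the study covariates;
* ``ipdw`` — inverse probability of data-source weighting of control
  outcomes toward the study covariate distribution;
* ``aipw`` — the augmented (efficient-influence-curve) estimator, doubly
  robust in (m0, m1) vs pi_d;
* ``tmle`` — targeted maximum likelihood: a one-parameter logistic
  fluctuation of the outcome fits along the clever covariate h(D, A, X) so
  the plug-in solves the influence-curve estimating equation;
* ``rct``  — the trial-only covariate-adjusted AIPW comparator.

Closed-form confidence intervals for aipw/tmle come from the influence
curve; the singly robust estimators use a stratified nonparametric
bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .data import HybridTrialData
from .nuisance import EstimationError, LearnerSpec, NuisanceFits, fit_nuisances

logger = logging.getLogger("hybridec")

__all__ = [
    "EffectEstimate",
    "mu1_hat",
    "estimate_mu0_om",
    "ipdw_weights",
    "estimate_mu0_ipdw",
    "dr_weights",
    "clever_covariate",
    "eic_value",
    "estimate_tau_om",
    "estimate_tau_ipdw",
    "estimate_tau_aipw",
    "tmle_fluctuate",
    "estimate_tau_tmle",
    "estimate_tau_rct",
    "closed_form_ci",
    "bootstrap_ci",
]


@dataclass
class EffectEstimate:
    """A treatment-effect estimate with uncertainty and provenance."""

    method: str
    tau_hat: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float
    p_value: float
    n_rct: int
    n_ec: int
    influence_values: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "tau_hat": self.tau_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "p_value": self.p_value,
            "n_rct": self.n_rct,
            "n_ec": self.n_ec,
        }


# ---------------------------------------------------------------------------
# Component estimators


def mu1_hat(data: HybridTrialData) -> float:
    """Treated-arm mean outcome; identifies E[Y^1 | D=1] under randomization."""
    treated = data.a == 1
    if treated.sum() == 0:
        raise EstimationError("no treated subjects")
    return float(data.y[treated].mean())


def estimate_mu0_om(data: HybridTrialData, fits: NuisanceFits) -> float:
    """g-computation: mean of m0-hat over the n_rct study subjects.

    External subjects contribute to m0-hat's training but are excluded
    from the averaging set.
    """
    if data.n_rct == 0:
        raise EstimationError("no study subjects")
    return float(fits.m0[data.d == 1].mean())


def ipdw_weights(data: HybridTrialData, fits: NuisanceFits) -> np.ndarray:
    """Inverse-probability-of-data-source weights.

    W_i = (1-A_i) pi_d(X_i) / { [1 - pi_a(X_i)] pi_d(X_i) + [1 - pi_d(X_i)] }.
    Treated subjects get weight 0; every control gets a positive weight.
    At pi_d = 1 this reduces to the classical within-trial weight
    (1-A) / (1-pi_a).
    """
    num = (1 - data.a) * fits.pi_d
    den = (1 - fits.pi_a) * fits.pi_d + (1 - fits.pi_d)
    return num / den


def estimate_mu0_ipdw(data: HybridTrialData, fits: NuisanceFits, normalize: bool = False) -> float:
    """Weighted control-outcome mean: n_rct^{-1} sum_i W_i Y_i.

    ``normalize`` switches to the Hajek form sum(W Y) / sum(W).
    """
    w = ipdw_weights(data, fits)
    if not (w > 0).any():
        raise EstimationError("all IPDW weights are zero")
    if normalize:
        return float(np.sum(w * data.y) / np.sum(w))
    return float(np.sum(w * data.y) / data.n_rct)


def dr_weights(a, d, pi_a, pi_d, r) -> np.ndarray:
    """Control-side weight W^dr of the efficient influence curve.

    W^dr = [ D(1-A) pi_d + (1-D)(1-A) pi_d r ] / [ pi_d (1-pi_a) + (1-pi_d) r ].
    The (1-A) factor zeroes treated subjects on both summands; with r = 1
    internal and external controls with equal pi_d receive equal weight.
    """
    a = np.asarray(a)
    d = np.asarray(d)
    num = (d * (1 - a) * pi_d) + ((1 - d) * (1 - a) * pi_d * r)
    den = pi_d * (1 - pi_a) + (1 - pi_d) * r
    return num / den


def clever_covariate(a, d, pi_a, pi_d, r, q) -> np.ndarray:
    """TMLE clever covariate h(D, A, X) = (1/q) { DA/pi_a - W^dr }."""
    a = np.asarray(a)
    d = np.asarray(d)
    return (d * a / pi_a - dr_weights(a, d, pi_a, pi_d, r)) / q


def eic_value(y, a, d, m1, m0, pi_a, pi_d, r, tau, q) -> float | np.ndarray:
    """Efficient influence curve phi(O; P) for tau (scalar or vectorized).

    phi = (1/q) { D [m1 - m0 - tau] + (DA/pi_a)[y - m1] - W^dr [y - m0] }.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    d = np.asarray(d)
    w = dr_weights(a, d, pi_a, pi_d, r)
    phi = (d * (m1 - m0 - tau) + d * a / pi_a * (y - m1) - w * (y - m0)) / q
    return float(phi) if phi.ndim == 0 else phi


def _influence(data: HybridTrialData, fits: NuisanceFits, m1, m0, tau: float) -> np.ndarray:
    q = data.n_rct / data.n
    return eic_value(data.y, data.a, data.d, m1, m0, fits.pi_a, fits.pi_d, fits.r, tau, q)


# ---------------------------------------------------------------------------
# Confidence intervals


def closed_form_ci(influence_values: np.ndarray, tau_hat: float, alpha: float = 0.05):
    """Normal interval tau_hat +/- z_{1-alpha/2} sd(phi)/sqrt(n) and its p-value."""
    phi = np.asarray(influence_values, dtype=float)
    if phi.size < 2:
        raise EstimationError("need at least 2 influence values")
    n = phi.size
    se = float(np.std(phi, ddof=1) / np.sqrt(n))
    z = float(stats.norm.ppf(1 - alpha / 2))
    lo, hi = tau_hat - z * se, tau_hat + z * se
    if se > 0:
        p = float(2 * stats.norm.sf(abs(tau_hat) / se))
    else:
        p = 0.0 if tau_hat != 0 else 1.0
    return lo, hi, se, p


def bootstrap_ci(
    data: HybridTrialData,
    estimator: str,
    spec: LearnerSpec | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    normalize: bool = False,
):
    """Stratified nonparametric percentile bootstrap for om / ipdw.

    Resamples with replacement independently within the trial (D=1) and
    external (D=0) samples, preserving n_rct and n_ec; nuisances are refit
    on each resample.  Resamples with an empty required stratum are
    redrawn (logged); the p-value comes from percentile-interval
    inversion.
    """
    if estimator not in ("om", "ipdw"):
        raise EstimationError("bootstrap_ci supports the singly robust estimators om/ipdw")
    spec = spec or LearnerSpec()
    rng = np.random.default_rng(seed)
    idx_rct = np.flatnonzero(data.d == 1)
    idx_ec = np.flatnonzero(data.d == 0)
    estimates = np.empty(B)
    redraws = 0
    for b in range(B):
        for _attempt in range(1000):
            take = np.concatenate(
                [rng.choice(idx_rct, size=idx_rct.size, replace=True)]
                + ([rng.choice(idx_ec, size=idx_ec.size, replace=True)] if idx_ec.size else [])
            )
            boot = data.subset(take)
            if (boot.a == 1).sum() >= 1 and ((boot.a == 0) & (boot.d == 1)).sum() >= 1:
                break
            redraws += 1
        else:
            raise EstimationError("bootstrap: could not draw a usable resample")
        fits = fit_nuisances(boot, spec=spec, k_folds=1, seed=int(rng.integers(2**31 - 1)))
        if estimator == "om":
            estimates[b] = mu1_hat(boot) - estimate_mu0_om(boot, fits)
        else:
            estimates[b] = mu1_hat(boot) - estimate_mu0_ipdw(boot, fits, normalize=normalize)
    if redraws:
        logger.info("bootstrap: %d redraw(s) due to empty strata", redraws)
        if redraws > 0.10 * B:
            logger.warning("bootstrap: > 10%% of resamples required redrawing")
    lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    left = (np.sum(estimates <= 0) + 1) / (B + 1)
    right = (np.sum(estimates >= 0) + 1) / (B + 1)
    p = min(1.0, 2 * min(left, right))
    return float(lo), float(hi), p, estimates


# ---------------------------------------------------------------------------
# Full estimators


def estimate_tau_om(
    data: HybridTrialData,
    fits: NuisanceFits,
    alpha: float = 0.05,
    boot_B: int = 0,
    seed: int = 0,
) -> EffectEstimate:
    """Outcome-model (g-computation) estimate with optional bootstrap CI."""
    tau = mu1_hat(data) - estimate_mu0_om(data, fits)
    return _singly_robust_estimate("om", tau, data, fits, alpha, boot_B, seed)


def estimate_tau_ipdw(
    data: HybridTrialData,
    fits: NuisanceFits,
    alpha: float = 0.05,
    boot_B: int = 0,
    seed: int = 0,
    normalize: bool = False,
) -> EffectEstimate:
    """IPDW estimate with optional bootstrap CI."""
    tau = mu1_hat(data) - estimate_mu0_ipdw(data, fits, normalize=normalize)
    return _singly_robust_estimate("ipdw", tau, data, fits, alpha, boot_B, seed, normalize)


def _singly_robust_estimate(method, tau, data, fits, alpha, boot_B, seed, normalize=False):
    se = float("nan")
    lo = hi = p = float("nan")
    meta = {"nuisance": fits.learner_spec.describe(), "q_hat": data.n_rct / data.n}
    if boot_B > 0:
        lo, hi, p, draws = bootstrap_ci(
            data, method, spec=fits.learner_spec, B=boot_B, alpha=alpha,
            seed=seed, normalize=normalize,
        )
        se = float(np.std(draws, ddof=1))
        meta["bootstrap_B"] = boot_B
    return EffectEstimate(
        method=method, tau_hat=float(tau), se=se, ci_low=lo, ci_high=hi,
        alpha=alpha, p_value=p, n_rct=data.n_rct, n_ec=data.n_ec, metadata=meta,
    )


def estimate_tau_aipw(data: HybridTrialData, fits: NuisanceFits, alpha: float = 0.05) -> EffectEstimate:
    """Augmented (one-step / estimating-equation) doubly robust estimate.

    tau-hat solves the empirical efficient-influence-curve equation, so the
    stored influence values average to zero by construction; the SE is
    sd(phi)/sqrt(n).
    """
    q = data.n_rct / data.n
    w = dr_weights(data.a, data.d, fits.pi_a, fits.pi_d, fits.r)
    contrib = (
        data.d * (fits.m1 - fits.m0)
        + data.d * data.a / fits.pi_a * (data.y - fits.m1)
        - w * (data.y - fits.m0)
    ) / q
    tau = float(contrib.mean())
    phi = _influence(data, fits, fits.m1, fits.m0, tau)
    lo, hi, se, p = closed_form_ci(phi, tau, alpha)
    return EffectEstimate(
        method="aipw", tau_hat=tau, se=se, ci_low=lo, ci_high=hi, alpha=alpha,
        p_value=p, n_rct=data.n_rct, n_ec=data.n_ec, influence_values=phi,
        metadata={
            "nuisance": fits.learner_spec.describe(),
            "k_folds": fits.k_folds,
            "trunc_eps": fits.trunc_eps,
            "q_hat": q,
            "seed": fits.seed,
        },
    )


@dataclass
class TmleFluctuation:
    """Result of the one-parameter logistic fluctuation."""

    m1_star: np.ndarray
    m0_star: np.ndarray
    epsilon: float
    lower: float
    upper: float


_SCALE_CLIP = 1e-6  # keeps logit(offset) finite for boundary predictions


def tmle_fluctuate(data: HybridTrialData, fits: NuisanceFits, delta: float = 0.0) -> TmleFluctuation:
    """Fluctuate the outcome fits along the clever covariate.

    The outcome and initial fits are mapped to [0, 1] via (v - L)/(U - L)
    with L = min(Y) - delta, U = max(Y) + delta; a single-parameter
    logistic regression of the scaled outcome on h(D, A, X) with offset
    logit(scaled m_A-hat) is fit on all subjects; predictions under A=1
    and A=0 are back-transformed.  One iteration solves the influence
    equation for the plug-in.
    """
    L = float(data.y.min()) - delta
    U = float(data.y.max()) + delta
    if U <= L:
        raise EstimationError("degenerate outcome: max(Y) must exceed min(Y)")
    span = U - L
    q = data.n_rct / data.n

    y_s = (data.y - L) / span
    m_obs = np.where(data.a == 1, fits.m1, fits.m0)
    off = logit(np.clip((m_obs - L) / span, _SCALE_CLIP, 1 - _SCALE_CLIP))
    h = clever_covariate(data.a, data.d, fits.pi_a, fits.pi_d, fits.r, q)

    model = sm.GLM(y_s, h[:, None], family=sm.families.Binomial(), offset=off)
    try:
        res = model.fit(maxiter=200, tol=1e-12)
    except Exception as exc:  # pragma: no cover - solver pathologies
        raise EstimationError(f"TMLE fluctuation failed to converge: {exc}") from exc
    if not res.converged:
        raise EstimationError("TMLE fluctuation did not converge")
    eps = float(res.params[0])

    h1 = clever_covariate(np.ones(data.n), data.d, fits.pi_a, fits.pi_d, fits.r, q)
    h0 = clever_covariate(np.zeros(data.n), data.d, fits.pi_a, fits.pi_d, fits.r, q)
    off1 = logit(np.clip((fits.m1 - L) / span, _SCALE_CLIP, 1 - _SCALE_CLIP))
    off0 = logit(np.clip((fits.m0 - L) / span, _SCALE_CLIP, 1 - _SCALE_CLIP))
    m1_star = L + span * expit(off1 + eps * h1)
    m0_star = L + span * expit(off0 + eps * h0)
    return TmleFluctuation(m1_star=m1_star, m0_star=m0_star, epsilon=eps, lower=L, upper=U)


def estimate_tau_tmle(
    data: HybridTrialData,
    fits: NuisanceFits,
    alpha: float = 0.05,
    delta: float = 0.0,
) -> EffectEstimate:
    """Targeted maximum likelihood estimate: plug-in of the fluctuated fits.

    tau-hat = n_rct^{-1} sum_i D_i [m1*(X_i) - m0*(X_i)]; as a plug-in of
    range-bounded predictions it respects the outcome's observed range.
    """
    if data.outcome_scale != "continuous":
        raise EstimationError("TMLE implemented for continuous outcomes")
    fl = tmle_fluctuate(data, fits, delta=delta)
    study = data.d == 1
    tau = float((fl.m1_star[study] - fl.m0_star[study]).mean())
    phi = _influence(data, fits, fl.m1_star, fl.m0_star, tau)
    lo, hi, se, p = closed_form_ci(phi, tau, alpha)
    return EffectEstimate(
        method="tmle", tau_hat=tau, se=se, ci_low=lo, ci_high=hi, alpha=alpha,
        p_value=p, n_rct=data.n_rct, n_ec=data.n_ec, influence_values=phi,
        metadata={
            "nuisance": fits.learner_spec.describe(),
            "k_folds": fits.k_folds,
            "trunc_eps": fits.trunc_eps,
            "q_hat": data.n_rct / data.n,
            "epsilon": fl.epsilon,
            "bounds": (fl.lower, fl.upper),
            "seed": fits.seed,
        },
    )


def estimate_tau_rct(
    data: HybridTrialData,
    fits: NuisanceFits | None = None,
    alpha: float = 0.05,
    spec: LearnerSpec | None = None,
    k_folds: int | None = None,
    seed: int | None = None,
) -> EffectEstimate:
    """Trial-only covariate-adjusted AIPW comparator.

    Discards external controls, refits the outcome models on trial data
    alone, fixes pi_d to exactly 1 and r to 1; the hybrid AIPW expression
    then reduces to the standard within-trial AIPW estimator with weights
    A/pi_a and (1-A)/(1-pi_a).
    """
    if fits is not None:
        spec = spec or fits.learner_spec
        k_folds = k_folds if k_folds is not None else fits.k_folds
        seed = seed if seed is not None else fits.seed
    spec = spec or LearnerSpec()
    k_folds = k_folds or 1
    seed = seed or 0
    trial = data.subset(data.d == 1)
    if (trial.a == 1).sum() < 1 or (trial.a == 0).sum() < 1:
        raise EstimationError("RCT-only estimator requires both arms in the trial")
    k_eff = min(k_folds, trial.n)
    trial_fits = fit_nuisances(trial, spec=spec, k_folds=k_eff, seed=seed, study_only=True)
    est = estimate_tau_aipw(trial, trial_fits, alpha=alpha)
    est.method = "rct_aipw"
    est.n_ec = data.n_ec
    return est


def estimate_all(
    data: HybridTrialData,
    spec: LearnerSpec | None = None,
    k_folds: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    boot_B: int = 1000,
    methods: tuple = ("rct", "om", "ipdw", "aipw", "tmle"),
) -> list[EffectEstimate]:
    """Run the comparator plus the four hybrid estimators on one dataset."""
    fits = fit_nuisances(data, spec=spec, k_folds=k_folds, seed=seed)
    out = []
    for m in methods:
        if m == "rct":
            out.append(estimate_tau_rct(data, fits, alpha=alpha))
        elif m == "om":
            out.append(estimate_tau_om(data, fits, alpha=alpha, boot_B=boot_B, seed=seed))
        elif m == "ipdw":
            out.append(estimate_tau_ipdw(data, fits, alpha=alpha, boot_B=boot_B, seed=seed))
        elif m == "aipw":
            out.append(estimate_tau_aipw(data, fits, alpha=alpha))
        elif m == "tmle":
            out.append(estimate_tau_tmle(data, fits, alpha=alpha))
        else:
            raise EstimationError(f"unknown method {m!r}")
    return out
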