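"""Cross-fitted nuisance models for hybrid-trial estimators.

Five nuisance functions feed the estimators: the arm-specific outcome
regressions m1(x) = E[Y|A=1,X=x] and m0(x) = E[Y|A=0,X=x] (the latter fit
on internal and external controls pooled), the study propensity score
pi_d(x) = Pr(D=1|X=x), the treatment propensity pi_a(x) = Pr(A=1|X,D=1)
(known by design), and the control-outcome variance ratio r between
sources.  Cross-fitting stores, for each subject, predictions from models
trained without that subject's fold, which is what licenses
machine-learning learners with root-n inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import clone, is_classifier
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from .data import HybridTrialData

__all__ = [
    "LearnerSpec",
    "NuisanceFits",
    "EstimationError",
    "fit_nuisances",
    "estimate_variance_ratio",
]

R_FLOOR = 1e-3


class EstimationError(RuntimeError):
    """Raised when a nuisance or effect estimate cannot be computed."""


@dataclass
class LearnerSpec:
    """Learner choice per nuisance function.

    ``m`` and ``pi_d`` name a built-in learner (``linear`` / ``logistic`` /
    ``random_forest``) or hold a scikit-learn estimator instance to be
    cloned.  ``r_mode`` selects the variance-ratio estimator:
    ``constant_one`` (homoscedastic default) or ``pooled_ratio``.
    """

    m: object = "linear"
    pi_d: object = "logistic"
    m_params: dict = field(default_factory=dict)
    pi_d_params: dict = field(default_factory=dict)
    r_mode: str = "constant_one"

    def describe(self) -> dict:
        def tag(v):
            return v if isinstance(v, str) else type(v).__name__

        return {
            "m": tag(self.m),
            "pi_d": tag(self.pi_d),
            "m_params": dict(self.m_params),
            "pi_d_params": dict(self.pi_d_params),
            "r_mode": self.r_mode,
        }


# Modest forest defaults keep repeated simulation studies desk-scale while
# remaining genuinely data-adaptive at trial-sized n; leaf size 5 smooths
# the per-tree fits so few trees suffice.
_RF_REG_DEFAULTS = dict(n_estimators=20, min_samples_leaf=5)
_RF_CLF_DEFAULTS = dict(n_estimators=20, min_samples_leaf=5)


def _make_regressor(spec: LearnerSpec, seed: int):
    if not isinstance(spec.m, str):
        return clone(spec.m)
    if spec.m == "linear":
        return LinearRegression(**spec.m_params)
    if spec.m == "random_forest":
        params = {**_RF_REG_DEFAULTS, **spec.m_params}
        return RandomForestRegressor(random_state=seed, **params)
    raise EstimationError(f"unknown outcome learner {spec.m!r}")


def _make_classifier(spec: LearnerSpec, seed: int):
    if not isinstance(spec.pi_d, str):
        return clone(spec.pi_d)
    if spec.pi_d == "logistic":
        # unpenalized maximum-likelihood logistic fit
        return LogisticRegression(C=np.inf, max_iter=2000, **spec.pi_d_params)
    if spec.pi_d == "random_forest":
        params = {**_RF_CLF_DEFAULTS, **spec.pi_d_params}
        return RandomForestClassifier(random_state=seed, **params)
    raise EstimationError(f"unknown propensity learner {spec.pi_d!r}")


def _predict_prob(model, x: np.ndarray) -> np.ndarray:
    if is_classifier(model):
        proba = model.predict_proba(x)
        idx = int(np.flatnonzero(model.classes_ == 1)[0])
        return proba[:, idx]
    return np.asarray(model.predict(x), dtype=float)


@dataclass
class NuisanceFits:
    """Per-subject (out-of-fold) nuisance predictions plus full-data models."""

    m1: np.ndarray
    m0: np.ndarray
    pi_d: np.ndarray
    pi_a: np.ndarray
    r: np.ndarray
    fold_id: np.ndarray
    learner_spec: LearnerSpec
    trunc_eps: float = 0.01
    k_folds: int = 1
    seed: int = 0
    m1_fn: Callable[[np.ndarray], np.ndarray] | None = None
    m0_fn: Callable[[np.ndarray], np.ndarray] | None = None
    pi_d_fn: Callable[[np.ndarray], np.ndarray] | None = None
    r_value: float = 1.0

    def __post_init__(self) -> None:
        if (self.r <= 0).any():
            raise EstimationError("variance ratio r must be strictly positive")

    @property
    def n(self) -> int:
        return self.m0.shape[0]


def _stratified_folds(a: np.ndarray, d: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded fold assignment stratified by (A, D) so every training split
    retains treated, internal-control and external-control units."""
    n = a.shape[0]
    fold = np.zeros(n, dtype=int)
    if k <= 1:
        return fold
    for aa, dd in ((1, 1), (0, 1), (0, 0)):
        idx = np.flatnonzero((a == aa) & (d == dd))
        if idx.size == 0:
            continue
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % k
    return fold


def fit_nuisances(
    data: HybridTrialData,
    spec: LearnerSpec | None = None,
    k_folds: int = 10,
    seed: int = 0,
    trunc_eps: float = 0.01,
    study_only: bool = False,
) -> NuisanceFits:
    """Fit (and optionally cross-fit) all nuisance functions.

    With ``k_folds > 1``, every subject's stored prediction comes from
    models trained on the other folds (fold assignment is a seeded random
    partition stratified by arm and source).  Propensity predictions are
    truncated into ``[trunc_eps, 1 - trunc_eps]``.  ``study_only`` fits on
    trial data alone with pi_d fixed to exactly 1 (the RCT-only
    comparator), bypassing both the propensity model and truncation.
    """
    spec = spec or LearnerSpec()
    n = data.n
    if not 1 <= k_folds <= n:
        raise EstimationError(f"k_folds must be in 1..{n}")
    if not 0.0 < trunc_eps < 0.5:
        raise EstimationError("trunc_eps must lie in (0, 0.5)")
    if (data.a == 1).sum() < 1 or (data.a == 0).sum() < 1:
        raise EstimationError("both treated and control subjects are required")

    rng = np.random.default_rng(seed)
    fold_id = _stratified_folds(data.a, data.d, k_folds, rng)
    m1_oof = np.empty(n)
    m0_oof = np.empty(n)
    pid_oof = np.ones(n)

    for f in range(k_folds):
        test = fold_id == f if k_folds > 1 else np.ones(n, dtype=bool)
        train = ~test if k_folds > 1 else np.ones(n, dtype=bool)
        tr_treated = train & (data.a == 1)
        tr_control = train & (data.a == 0)
        if tr_treated.sum() == 0 or tr_control.sum() == 0:
            raise EstimationError(f"fold {f}: empty treated or control training stratum")
        fit_seed = int(rng.integers(2**31 - 1))
        m1_model = _make_regressor(spec, fit_seed).fit(data.x[tr_treated], data.y[tr_treated])
        m0_model = _make_regressor(spec, fit_seed + 1).fit(data.x[tr_control], data.y[tr_control])
        m1_oof[test] = np.asarray(m1_model.predict(data.x[test]), dtype=float)
        m0_oof[test] = np.asarray(m0_model.predict(data.x[test]), dtype=float)
        if not study_only:
            if len(np.unique(data.d[train])) < 2:
                raise EstimationError(f"fold {f}: training split lacks a source class")
            pid_model = _make_classifier(spec, fit_seed + 2).fit(data.x[train], data.d[train])
            pid_oof[test] = _predict_prob(pid_model, data.x[test])

    # Full-data refits, used by diagnostics and the variance-ratio
    # estimator; fit lazily on first call to keep replicated studies cheap.
    full_seed = int(np.random.default_rng(seed).integers(2**31 - 1))

    def _lazy_predictor(builder):
        cache = {}

        def predict(x):
            if "model" not in cache:
                cache["model"] = builder()
            return cache["model"](np.atleast_2d(x))

        return predict

    def _build_m(arm_mask, fit_seed):
        model = _make_regressor(spec, fit_seed).fit(data.x[arm_mask], data.y[arm_mask])
        return lambda x: np.asarray(model.predict(x), dtype=float)

    m1_fn = _lazy_predictor(lambda: _build_m(data.a == 1, full_seed))
    m0_fn = _lazy_predictor(lambda: _build_m(data.a == 0, full_seed + 1))
    if study_only:
        pi_d_fn = lambda x: np.ones(np.atleast_2d(x).shape[0])
    else:
        def _build_pid():
            model = _make_classifier(spec, full_seed + 2).fit(data.x, data.d)
            return lambda x: np.clip(_predict_prob(model, x), trunc_eps, 1 - trunc_eps)

        pi_d_fn = _lazy_predictor(_build_pid)
        pid_oof = np.clip(pid_oof, trunc_eps, 1 - trunc_eps)

    pi_a = np.clip(data.pi_a_values(), trunc_eps, 1 - trunc_eps)

    if spec.r_mode == "constant_one":
        r_value = 1.0
    else:
        _, r_value = estimate_variance_ratio(data, m0_fn, spec.r_mode)
    return NuisanceFits(
        m1=m1_oof,
        m0=m0_oof,
        pi_d=pid_oof,
        pi_a=pi_a,
        r=np.full(n, r_value),
        fold_id=fold_id,
        learner_spec=spec,
        trunc_eps=trunc_eps,
        k_folds=k_folds,
        seed=seed,
        m1_fn=m1_fn,
        m0_fn=m0_fn,
        pi_d_fn=pi_d_fn,
        r_value=r_value,
    )


def estimate_variance_ratio(
    data: HybridTrialData,
    m0_fn: Callable[[np.ndarray], np.ndarray],
    mode: str = "constant_one",
):
    """Estimate the control-outcome variance ratio between sources.

    ``constant_one`` returns r = 1 (homoscedastic across sources).
    ``pooled_ratio`` returns the constant (mean squared residual of
    internal controls about m0) / (same for external controls), floored at
    a small positive constant.  Returns ``(function, value)``.
    """
    if mode == "constant_one":
        value = 1.0
    elif mode == "pooled_ratio":
        ic = (data.d == 1) & (data.a == 0)
        ec = data.d == 0
        if ec.sum() == 0 or ic.sum() == 0:
            raise EstimationError("pooled_ratio requires controls in both sources")
        res_ic = data.y[ic] - m0_fn(data.x[ic])
        res_ec = data.y[ec] - m0_fn(data.x[ec])
        denom = float(np.mean(res_ec**2))
        value = float(np.mean(res_ic**2)) / max(denom, R_FLOOR)
        value = max(value, R_FLOOR)
    else:
        raise EstimationError(f"unknown variance-ratio mode {mode!r}")

    def r_fn(x: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(x).shape[0], value)

    return r_fn, value
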