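"""Synthetic hybrid-trial generator and simulation studies.

The generator emulates a rare-disease hybrid design: 150 trial subjects
randomized 2:1 to treatment plus 50 external controls on a continuous
endpoint.  Covariates are two standard normals and two Bernoulli(1/2)
indicators; source membership follows a logistic study propensity score
(non-constant, so treatment and source are dependent); the control
outcome surface is linear with optional quadratic and interaction terms
("nonlinear truth") so that linear analyst models can be genuinely
misspecified; noise is Gaussian.  Mean exchangeability across sources
holds by construction unless an explicit shift ``u_shift`` is injected
for sensitivity-analysis testing.

Five analysis settings pair a truth with analyst learners:

1. linear truth, correctly specified linear/logistic nuisances;
2. nonlinear truth, misspecified linear study propensity + random-forest
   outcome models (outcome-model estimator omitted);
3. nonlinear truth, misspecified linear outcome models + random-forest
   study propensity (IPDW omitted);
4. nonlinear truth, both nuisances misspecified linear;
5. nonlinear truth, both nuisances random forests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import HybridTrialData
from .estimators import (
    estimate_tau_aipw,
    estimate_tau_ipdw,
    estimate_tau_om,
    estimate_tau_rct,
    estimate_tau_tmle,
)
from .nuisance import EstimationError, LearnerSpec, fit_nuisances

logger = logging.getLogger("hybridec")

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationError",
    "setting_spec",
    "setting_config",
    "setting_methods",
    "simulate_trial",
    "run_study",
    "power_analysis",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Data-generating parameters for one synthetic hybrid trial.

    ``alpha0`` + ``alpha_lin`` (+ ``alpha_quad`` x1^2) parameterize the
    logistic study propensity; ``beta0`` + ``beta`` (+ ``gamma`` =
    (coef on x1^2, coef on x1*x2)) the control outcome mean.  ``tau`` is a
    homogeneous additive effect unless ``tau_slope`` is nonzero, in which
    case tau(x) = tau + tau_slope * x1.  ``u_shift`` lowers external
    controls' outcomes by a constant, injecting a known violation of mean
    exchangeability.
    """

    n_rct: int = 150
    n_ec: int = 50
    pi_a: float = 2.0 / 3.0  # 2:1 randomization
    tau: float = 1.0
    tau_slope: float = 0.0
    noise_sd: float = 1.0
    alpha0: float = 1.0
    alpha_lin: tuple = (0.5, -0.3, 0.0, 0.0)
    alpha_quad: float = 0.0
    beta0: float = 1.0
    beta: tuple = (1.0, 0.5, -0.5, 0.5)
    gamma: tuple = (0.0, 0.0)
    u_shift: float = 0.0

    @property
    def p(self) -> int:
        return len(self.beta)

    def pi_d(self, x: np.ndarray) -> np.ndarray:
        lin = self.alpha0 + x @ np.asarray(self.alpha_lin) + self.alpha_quad * x[:, 0] ** 2
        return expit(lin)

    def m0(self, x: np.ndarray) -> np.ndarray:
        return (
            self.beta0
            + x @ np.asarray(self.beta)
            + self.gamma[0] * x[:, 0] ** 2
            + self.gamma[1] * x[:, 0] * x[:, 1]
        )

    def tau_x(self, x: np.ndarray) -> np.ndarray:
        return self.tau + self.tau_slope * x[:, 0]


_NONLINEAR = dict(alpha_quad=-0.5, gamma=(0.7, 0.5))


def setting_config(setting: int, **overrides) -> SimulationConfig:
    """Data-generating truth for an analysis setting (1 = linear truth,
    2-5 = nonlinear truth)."""
    if setting not in (1, 2, 3, 4, 5):
        raise SimulationError("setting must be in 1..5")
    base = SimulationConfig(**overrides)
    if setting == 1:
        return base
    return replace(base, **_NONLINEAR)


def setting_spec(setting: int) -> LearnerSpec:
    """Analyst learner choices for an analysis setting."""
    if setting == 1:
        return LearnerSpec(m="linear", pi_d="logistic")
    if setting == 2:
        return LearnerSpec(m="random_forest", pi_d="logistic")
    if setting == 3:
        return LearnerSpec(m="linear", pi_d="random_forest")
    if setting == 4:
        return LearnerSpec(m="linear", pi_d="logistic")
    if setting == 5:
        return LearnerSpec(m="random_forest", pi_d="random_forest")
    raise SimulationError("setting must be in 1..5")


def setting_methods(setting: int) -> tuple:
    """Estimators reported per setting (the singly robust method whose
    nuisance is machine-learned has no valid closed-form/bootstrap CI and
    is omitted)."""
    if setting == 2:
        return ("rct", "ipdw", "aipw", "tmle")
    if setting == 3:
        return ("rct", "om", "aipw", "tmle")
    return ("rct", "om", "ipdw", "aipw", "tmle")


def _draw_covariates(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    x = np.empty((n, p))
    x[:, 0] = rng.standard_normal(n)
    x[:, 1] = rng.standard_normal(n) if p > 1 else 0.0
    for j in range(2, p):
        x[:, j] = rng.integers(0, 2, size=n)
    return x


def simulate_trial(config: SimulationConfig, seed: int = 0) -> HybridTrialData:
    """Draw one synthetic hybrid trial with exactly the configured counts.

    Source membership is sampled as D ~ Bernoulli(pi_d(x)) with rejection
    until n_rct study subjects and n_ec external controls accumulate;
    treatment is randomized Bernoulli(pi_a) within the trial; external
    controls are untreated.
    """
    rng = np.random.default_rng(seed)
    need_rct, need_ec = config.n_rct, config.n_ec
    xs_rct, xs_ec = [], []
    got_rct = got_ec = 0
    for _ in range(500):
        batch = max(2 * (need_rct + need_ec), 256)
        x = _draw_covariates(rng, batch, config.p)
        d = rng.random(batch) < config.pi_d(x)
        if got_rct < need_rct:
            take = x[d][: need_rct - got_rct]
            xs_rct.append(take)
            got_rct += take.shape[0]
        if got_ec < need_ec:
            take = x[~d][: need_ec - got_ec]
            xs_ec.append(take)
            got_ec += take.shape[0]
        if got_rct >= need_rct and got_ec >= need_ec:
            break
    else:
        raise SimulationError(
            "could not reach the requested source counts; adjust alpha0 toward balance"
        )
    x = np.vstack([np.vstack(xs_rct) if xs_rct else np.empty((0, config.p))]
                  + ([np.vstack(xs_ec)] if xs_ec else []))
    d = np.concatenate([np.ones(need_rct, dtype=int), np.zeros(need_ec, dtype=int)])
    a = np.zeros(need_rct + need_ec, dtype=int)
    a[:need_rct] = rng.random(need_rct) < config.pi_a

    m0 = config.m0(x)
    y = m0 + config.tau_x(x) * a + config.noise_sd * rng.standard_normal(x.shape[0])
    y = y - config.u_shift * (d == 0)
    return HybridTrialData(
        y=y, a=a, d=d, x=x,
        covariate_names=[f"x{j + 1}" for j in range(config.p)],
        pi_a_design=config.pi_a,
    )


@dataclass
class SimulationResult:
    """Aggregated operating characteristics of a simulation study."""

    table: pd.DataFrame
    n_reps: int
    seed: int
    n_failures: int = 0
    config: SimulationConfig | None = None
    raw: dict = field(default_factory=dict)


_ESTIMATOR_FN = {
    "om": lambda data, fits, alpha: estimate_tau_om(data, fits, alpha=alpha),
    "ipdw": lambda data, fits, alpha: estimate_tau_ipdw(data, fits, alpha=alpha),
    "aipw": estimate_tau_aipw,
    "tmle": estimate_tau_tmle,
    "rct": lambda data, fits, alpha: estimate_tau_rct(data, fits, alpha=alpha),
}


def run_study(
    config: SimulationConfig,
    methods=("rct", "om", "ipdw", "aipw", "tmle"),
    n_reps: int = 1000,
    seed: int = 0,
    spec: LearnerSpec | None = None,
    k_folds: int = 10,
    alpha: float = 0.05,
) -> SimulationResult:
    """Replicate simulate -> fit -> estimate and aggregate bias/MSE/coverage.

    Coverage and rejection are recorded for the influence-curve methods
    (rct, aipw, tmle); the singly robust estimators contribute bias/MSE
    (their bootstrap intervals are too costly to replicate here and are
    available through :func:`hybridec.estimators.bootstrap_ci`).
    """
    bad = set(methods) - set(_ESTIMATOR_FN)
    if bad:
        raise SimulationError(f"unknown method(s): {sorted(bad)}")
    spec = spec or LearnerSpec()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(2**31 - 1, size=n_reps)
    true_tau = config.tau  # homogeneous-effect default
    taus = {m: [] for m in methods}
    covers = {m: [] for m in methods}
    rejects = {m: [] for m in methods}
    ses = {m: [] for m in methods}
    n_fail = 0
    for r in range(n_reps):
        s = int(rep_seeds[r])
        try:
            data = simulate_trial(config, seed=s)
            fits = fit_nuisances(data, spec=spec, k_folds=k_folds, seed=s)
            for m in methods:
                est = _ESTIMATOR_FN[m](data, fits, alpha)
                taus[m].append(est.tau_hat)
                if np.isfinite(est.ci_low):
                    covers[m].append(est.ci_low <= true_tau <= est.ci_high)
                    rejects[m].append(est.p_value < alpha)
                    ses[m].append(est.se)
        except (EstimationError, SimulationError) as exc:
            n_fail += 1
            logger.info("replicate %d failed: %s", r, exc)
    if n_fail > 0.01 * n_reps:
        logger.warning("simulation: %d/%d replicates failed", n_fail, n_reps)

    rows = []
    for m in methods:
        t = np.asarray(taus[m], dtype=float)
        row = {
            "method": m,
            "n_ok": t.size,
            "bias": float(t.mean() - true_tau) if t.size else np.nan,
            "mse": float(np.mean((t - true_tau) ** 2)) if t.size else np.nan,
            "sd": float(t.std(ddof=1)) if t.size > 1 else np.nan,
            "coverage": float(np.mean(covers[m])) if covers[m] else np.nan,
            "rejection_rate": float(np.mean(rejects[m])) if rejects[m] else np.nan,
            "mean_se": float(np.mean(ses[m])) if ses[m] else np.nan,
        }
        rows.append(row)
    table = pd.DataFrame(rows).set_index("method")
    return SimulationResult(
        table=table, n_reps=n_reps, seed=seed, n_failures=n_fail, config=config,
        raw={"tau_hat": {m: np.asarray(v) for m, v in taus.items()}},
    )


def power_analysis(
    config: SimulationConfig,
    tau_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_ec_grid=None,
    n_reps: int = 500,
    seed: int = 0,
    spec: LearnerSpec | None = None,
    k_folds: int = 10,
    methods=("rct", "aipw", "tmle"),
    alpha: float = 0.05,
) -> SimulationResult:
    """Rejection rate of H0: tau = 0 over effect-size and n_ec grids.

    At tau = 0 the rejection rate is the type-I error; power should be
    nondecreasing in both the effect size and the external-control count.
    """
    n_ec_grid = [config.n_ec] if n_ec_grid is None else list(n_ec_grid)
    rng = np.random.default_rng(seed)
    rows = []
    for tau in tau_grid:
        for n_ec in n_ec_grid:
            cfg = replace(config, tau=float(tau), n_ec=int(n_ec))
            sub_seed = int(rng.integers(2**31 - 1))
            res = run_study(
                cfg, methods=methods, n_reps=n_reps, seed=sub_seed,
                spec=spec, k_folds=k_folds, alpha=alpha,
            )
            for m in methods:
                rows.append(
                    {
                        "tau": float(tau),
                        "n_ec": int(n_ec),
                        "method": m,
                        "rejection_rate": float(res.table.loc[m, "rejection_rate"]),
                        "n_ok": int(res.table.loc[m, "n_ok"]),
                    }
                )
    return SimulationResult(
        table=pd.DataFrame(rows), n_reps=n_reps, seed=seed, config=config,
    )
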