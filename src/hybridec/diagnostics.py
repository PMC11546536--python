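"""Covariate-balance diagnostics and sensitivity analysis for borrowing
external controls.

Balance between the internal and external control arms is summarized by
the multivariate normalized difference of covariate means and by the
difference in mean estimated study propensity scores (values above 0.25
are flagged, never used as a gate).  The borrowing assumption's testable
implication — equal control-arm outcome regressions across sources — is
visualized by binning controls on the estimated study propensity score.
Violations are propagated through a plug-in estimate of the asymptotic
bias E[Pr(D=0|A=0,X) u(X) | D=1] and a tipping-point analysis for a
constant violation magnitude B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .data import HybridTrialData
from .estimators import EffectEstimate
from .nuisance import EstimationError, LearnerSpec, NuisanceFits, _make_regressor

__all__ = [
    "normalized_difference",
    "propensity_imbalance",
    "a4_bin_diagnostic",
    "plot_a4_bins",
    "SensitivityResult",
    "estimate_bias_bound",
    "tipping_point",
    "shifted_ci",
    "PI_D_IMBALANCE_FLAG",
]

PI_D_IMBALANCE_FLAG = 0.25


def normalized_difference(x1: np.ndarray, x0: np.ndarray) -> float:
    """Multivariate normalized difference between two covariate samples.

    sqrt( 2 (xbar1 - xbar0)' (S1 + S0)^{-1} (xbar1 - xbar0) ) with sample
    covariance matrices S1, S0.  By convention group 1 is the internal
    control arm and group 0 the external controls.  Affine-invariant under
    a common nonsingular map of both samples.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if x1.shape[1] != x0.shape[1]:
        raise ValueError("covariate dimension mismatch between groups")
    if x1.shape[0] < 2 or x0.shape[0] < 2:
        raise ValueError("each group needs at least 2 rows")
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    s = np.cov(x1, rowvar=False) + np.cov(x0, rowvar=False)
    s = np.atleast_2d(s)
    try:
        sol = np.linalg.solve(s, diff)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; using pseudo-inverse")
        sol = np.linalg.pinv(s) @ diff
    return float(np.sqrt(max(2.0 * diff @ sol, 0.0)))


def propensity_imbalance(data: HybridTrialData, fits: NuisanceFits) -> float:
    """Difference in mean estimated study propensity score between sources.

    n_rct^{-1} sum D_i pi_d(X_i) - n_ec^{-1} sum (1-D_i) pi_d(X_i); zero
    under identical covariate distributions.  Values above 0.25 are
    conventionally flagged as substantial imbalance.
    """
    if data.n_ec == 0:
        raise EstimationError("propensity imbalance requires external controls")
    study = fits.pi_d[data.d == 1].mean()
    external = fits.pi_d[data.d == 0].mean()
    return float(study - external)


def a4_bin_diagnostic(
    data: HybridTrialData,
    fits: NuisanceFits,
    bin_width: float = 0.05,
    z: float | None = None,
) -> pd.DataFrame:
    """Mean control outcome by study-propensity bin and source.

    Controls only are bucketed by pi_d-hat into fixed-width bins; per bin
    and source the count, mean outcome and a normal 95% CI are reported
    (no CI for singleton cells).  Under mean exchangeability the two
    sources should agree within sampling error bin by bin.
    """
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must lie in (0, 1]")
    z = float(stats.norm.ppf(0.975)) if z is None else z
    ctrl = data.a == 0
    if (ctrl & (data.d == 1)).sum() == 0 or (ctrl & (data.d == 0)).sum() == 0:
        warnings.warn("controls missing in one source; diagnostic table may be empty")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    rows = []
    bins = np.clip(np.digitize(fits.pi_d, edges) - 1, 0, len(edges) - 2)
    for b in np.unique(bins[ctrl]):
        for dd, label in ((1, "internal"), (0, "external")):
            sel = ctrl & (data.d == dd) & (bins == b)
            n = int(sel.sum())
            if n == 0:
                continue
            mean_y = float(data.y[sel].mean())
            if n >= 2:
                half = z * float(data.y[sel].std(ddof=1)) / np.sqrt(n)
                lo, hi = mean_y - half, mean_y + half
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "bin_low": float(edges[b]),
                    "bin_high": float(edges[b + 1]),
                    "group": label,
                    "n": n,
                    "mean_y": mean_y,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "group", "n", "mean_y", "ci_lo", "ci_hi"])


def plot_a4_bins(table: pd.DataFrame, path=None):
    """Plot the binned control-outcome comparison (internal vs external).

    Sources are dodged within each study-propensity bin; error bars show
    the per-cell normal 95% CI where available.  Returns the figure;
    saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    offsets = {"internal": -0.004, "external": 0.004}
    colors = {"internal": "tab:blue", "external": "tab:orange"}
    for group, sub in table.groupby("group"):
        center = (sub.bin_low + sub.bin_high) / 2 + offsets.get(group, 0.0)
        err = np.where(
            np.isfinite(sub.ci_lo), sub.mean_y - sub.ci_lo, 0.0
        )
        ax.errorbar(center, sub.mean_y, yerr=err, fmt="o", capsize=3,
                    label=f"{group} controls", color=colors.get(group))
    ax.set_xlabel("estimated study propensity score bin")
    ax.set_ylabel("mean outcome among controls")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass
class SensitivityResult:
    """Plug-in bias estimate and tipping-point inputs for A4 violations."""

    bias_hat: float
    u_hat: Callable[[np.ndarray], np.ndarray] | None
    pr_d0_given_a0: float
    mean_u_study: float
    factored_bound: float

    def as_dict(self) -> dict:
        return {
            "bias_hat": self.bias_hat,
            "pr_d0_given_a0": self.pr_d0_given_a0,
            "mean_u_study": self.mean_u_study,
            "factored_bound": self.factored_bound,
        }


def estimate_bias_bound(
    data: HybridTrialData,
    spec: LearnerSpec | None = None,
    min_controls: int = 10,
    seed: int = 0,
) -> SensitivityResult:
    """Plug-in estimate of the asymptotic bias from violated exchangeability.

    Fits E[Y|A=0,D=1,X] and E[Y|A=0,D=0,X] separately, with their
    difference u-hat, and Pr(D=0|A=0,X) on the pooled controls; returns
    the average of their product over study subjects (``bias_hat``)
    together with the factored form Pr(D=0|A=0) * E[u-hat(X)|D=1].
    """
    spec = spec or LearnerSpec()
    ic = (data.d == 1) & (data.a == 0)
    ec = data.d == 0
    if ic.sum() < min_controls or ec.sum() < min_controls:
        raise EstimationError(
            f"need >= {min_controls} controls per source to fit u(x); "
            "consider the constant-B mode (tipping_point)"
        )
    m_ic = _make_regressor(spec, seed).fit(data.x[ic], data.y[ic])
    m_ec = _make_regressor(spec, seed + 1).fit(data.x[ec], data.y[ec])

    def u_hat(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return np.asarray(m_ic.predict(x), dtype=float) - np.asarray(m_ec.predict(x), dtype=float)

    ctrl = data.a == 0
    clf = LogisticRegression(C=np.inf, max_iter=2000)
    clf.fit(data.x[ctrl], (data.d[ctrl] == 0).astype(int))
    idx1 = int(np.flatnonzero(clf.classes_ == 1)[0])

    study = data.d == 1
    pr_d0_x = clf.predict_proba(data.x[study])[:, idx1]
    u_study = u_hat(data.x[study])
    bias_hat = float(np.mean(pr_d0_x * u_study))
    pr_d0 = float(ec.sum() / ctrl.sum())
    mean_u = float(u_study.mean())
    return SensitivityResult(
        bias_hat=bias_hat,
        u_hat=u_hat,
        pr_d0_given_a0=pr_d0,
        mean_u_study=mean_u,
        factored_bound=pr_d0 * mean_u,
    )


def shifted_ci(estimate: EffectEstimate, pr_d0_given_a0: float, B: float):
    """Confidence interval shifted by a constant exchangeability violation.

    A violation u(X) = B (external controls' control-outcome mean lower by
    B) biases the estimate by sign(tau) * Pr(D=0|A=0) * B toward the
    finding; the shifted interval removes it, preserving the width.
    """
    shift = np.sign(estimate.tau_hat) * pr_d0_given_a0 * B
    return estimate.ci_low - shift, estimate.ci_high - shift


def tipping_point(estimate: EffectEstimate, pr_d0_given_a0: float) -> float:
    """Smallest constant violation magnitude B that overturns significance.

    Solves for the minimal |B| such that the interval shifted by
    -sign(tau) * Pr(D=0|A=0) * B includes zero; 0 if the interval already
    contains zero.  Closed form: the near-zero interval endpoint divided
    by Pr(D=0|A=0).
    """
    if not 0.0 < pr_d0_given_a0 < 1.0:
        raise ValueError("pr_d0_given_a0 must lie in (0, 1)")
    lo, hi = estimate.ci_low, estimate.ci_high
    if lo <= 0.0 <= hi:
        return 0.0
    endpoint = lo if estimate.tau_hat > 0 else -hi
    return float(abs(endpoint) / pr_d0_given_a0)
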