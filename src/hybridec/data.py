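"""Observed-data container for hybrid trials with external controls.

A hybrid trial pools ``n_rct`` subjects from a randomized trial (source
indicator ``d = 1``) with ``n_ec`` external controls (``d = 0``).  Each
subject contributes an outcome ``y``, a binary treatment ``a`` (external
controls are never treated), and baseline covariates ``x``.  The
within-trial randomization probability ``pi_a_design`` is known by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridec")

__all__ = ["HybridTrialData", "DataError", "ConfigError", "load_table"]


class DataError(ValueError):
    """Raised when subject-level records violate the hybrid-trial design."""


class ConfigError(ValueError):
    """Raised for malformed configuration (column maps, parameters)."""


@dataclass
class HybridTrialData:
    """The observed vector O = (Y, X, A, D) for all subjects plus design knowledge.

    Parameters
    ----------
    y : outcome vector, length n.
    a : binary treatment vector (1 = experimental arm).
    d : binary source vector (1 = randomized trial, 0 = external control).
    x : covariate matrix, n rows by p columns.
    covariate_names : names of the p covariate columns.
    pi_a_design : the known randomization probability Pr(A=1 | X, D=1);
        either a scalar in (0, 1) or a callable mapping the covariate
        matrix to a vector of probabilities.
    outcome_scale : "continuous" or "binary".
    """

    y: np.ndarray
    a: np.ndarray
    d: np.ndarray
    x: np.ndarray
    covariate_names: Sequence[str] = ()
    pi_a_design: float | Callable[[np.ndarray], np.ndarray] = 0.5
    outcome_scale: str = "continuous"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.a = np.asarray(self.a).ravel()
        self.d = np.asarray(self.d).ravel()
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[0] != self.y.shape[0]:
            self.x = self.x.T
        n = self.y.shape[0]
        if not (self.a.shape[0] == self.d.shape[0] == self.x.shape[0] == n):
            raise DataError("y, a, d, x must have one entry/row per subject")
        for name, v in (("a", self.a), ("d", self.d)):
            if not np.isin(v, (0, 1)).all():
                raise DataError(f"{name} must be coded 0/1; got {set(np.unique(v))}")
        self.a = self.a.astype(int)
        self.d = self.d.astype(int)
        if np.isnan(self.y).any() or np.isnan(self.x).any():
            raise DataError("missing values present; loader enforces complete cases")
        bad = np.flatnonzero((self.d == 0) & (self.a == 1))
        if bad.size:
            raise DataError(
                f"external controls must be untreated (D=0 implies A=0); "
                f"violated at row(s) {bad.tolist()}"
            )
        if self.d.sum() < 1:
            raise DataError("at least one randomized-trial subject (D=1) required")
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.x.shape[1])]
        self.covariate_names = list(self.covariate_names)
        if len(self.covariate_names) != self.x.shape[1]:
            raise DataError("covariate_names length must match x columns")
        if np.isscalar(self.pi_a_design):
            if not 0.0 < float(self.pi_a_design) < 1.0:
                raise DataError("pi_a_design must lie strictly in (0, 1)")
        if self.outcome_scale not in ("continuous", "binary"):
            raise DataError("outcome_scale must be 'continuous' or 'binary'")

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_rct(self) -> int:
        return int(self.d.sum())

    @property
    def n_ec(self) -> int:
        return int(self.n - self.d.sum())

    @property
    def p(self) -> int:
        return self.x.shape[1]

    def pi_a_values(self) -> np.ndarray:
        """Design randomization probability evaluated for every subject."""
        if callable(self.pi_a_design):
            v = np.asarray(self.pi_a_design(self.x), dtype=float).ravel()
            if v.shape[0] != self.n:
                raise DataError("pi_a_design callable must return one value per subject")
        else:
            v = np.full(self.n, float(self.pi_a_design))
        if ((v <= 0) | (v >= 1)).any():
            raise DataError("pi_a_design values must lie strictly in (0, 1)")
        return v

    def subset(self, mask: np.ndarray) -> "HybridTrialData":
        """Return a new container restricted to ``mask`` (boolean or index)."""
        mask = np.asarray(mask)
        return HybridTrialData(
            y=self.y[mask],
            a=self.a[mask],
            d=self.d[mask],
            x=self.x[mask],
            covariate_names=self.covariate_names,
            pi_a_design=self.pi_a_design,
            outcome_scale=self.outcome_scale,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.x, columns=self.covariate_names)
        df.insert(0, "d", self.d)
        df.insert(0, "a", self.a)
        df.insert(0, "y", self.y)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_table(
    path,
    column_map: dict | None = None,
    pi_a: float | Callable = 0.5,
    outcome_scale: str = "continuous",
) -> HybridTrialData:
    """Load a delimited text table into a validated :class:`HybridTrialData`.

    ``column_map`` maps the roles ``y``, ``a``, ``d`` to column names and
    ``x`` to a list of covariate column names; unmapped roles default to
    columns named ``y``/``a``/``d`` with every remaining column treated as
    a covariate.  Rows with any missing mapped value are dropped
    (complete-case analysis) and the dropped count is logged.
    """
    df = pd.read_csv(path)
    column_map = dict(column_map or {})
    y_col = column_map.get("y", "y")
    a_col = column_map.get("a", "a")
    d_col = column_map.get("d", "d")
    for role, col in (("y", y_col), ("a", a_col), ("d", d_col)):
        if col not in df.columns:
            raise ConfigError(f"column {col!r} (role {role!r}) not found in {path}")
    x_cols = column_map.get("x")
    if x_cols is None:
        x_cols = [c for c in df.columns if c not in (y_col, a_col, d_col)]
    missing = [c for c in x_cols if c not in df.columns]
    if missing:
        raise ConfigError(f"covariate column(s) {missing} not found in {path}")

    used = [y_col, a_col, d_col, *x_cols]
    sub = df[used].apply(pd.to_numeric, errors="coerce")
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("load_table: dropped %d incomplete row(s) of %d", n_dropped, len(sub))
    sub = sub[complete]
    if sub.empty:
        raise DataError("no complete-case rows remain after filtering")

    a = sub[a_col].to_numpy()
    d = sub[d_col].to_numpy()
    for role, v in (("a", a), ("d", d)):
        if not np.isin(v, (0, 1)).all():
            raise DataError(f"column for {role!r} must be coded 0/1")
    return HybridTrialData(
        y=sub[y_col].to_numpy(dtype=float),
        a=a.astype(int),
        d=d.astype(int),
        x=sub[x_cols].to_numpy(dtype=float),
        covariate_names=list(x_cols),
        pi_a_design=pi_a,
        outcome_scale=outcome_scale,
    )
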