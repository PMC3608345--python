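"""Leave-one-out cross-validation (PRESS) and duplicate-measurement error.

PRESS is the sum of squared leave-one-out prediction residuals,
sum_i (y_i - yhat_(i))^2, where yhat_(i) is the prediction for subject i from
the model refitted without subject i.  For a least-squares fit the LOO
residual equals e_i / (1 - h_ii) with h_ii the leverage, so PRESS is computed
from a single fit; :func:`press_naive` performs the literal n refits and is
kept as an independent cross-check.

The cross-validated coefficient of determination is
R2_PRESS = 1 - PRESS / ((n-1) * var(y)) — always against the centered total
sum of squares, for both intercept and no-intercept models.  It may be
negative for models that predict worse than the response mean; such values
are reported as-is.

``rmse_press = sqrt(PRESS/n)`` is this package's per-observation error
summary for the leave-one-out residuals.

Technical error of measurement (TEM) for duplicate measurements uses the
Dahlberg form sqrt(sum d_i^2 / 2m) over m pairs, with TEM% = 100*TEM/mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import MultivariateFit, _as_frame, fit_multivariate_least_squares

__all__ = [
    "PressResult",
    "TemResult",
    "press_loo",
    "press_naive",
    "r2_press",
    "r2_press_from_summary",
    "technical_error",
]

_LEVERAGE_TOL = 1e-8


@dataclass
class PressResult:
    """Per-response PRESS (kg^2), R2_PRESS and rmse_press (kg)."""

    press: pd.Series
    r2_press: pd.Series
    rmse_press: pd.Series
    loo_residuals: pd.DataFrame


def r2_press(press: float, y) -> float:
    """Cross-validated R^2: 1 - PRESS / ((n-1) * var(y))."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("response has zero variance; R2_PRESS is undefined")
    return 1.0 - press / tss


def r2_press_from_summary(press: float, n: int, sd: float) -> float:
    """R2_PRESS from summary statistics: 1 - PRESS / ((n-1) * sd^2)."""
    if n < 2:
        raise ValueError("need at least 2 observations")
    if sd <= 0:
        raise ValueError("response SD must be positive")
    return 1.0 - press / ((n - 1) * sd**2)


def _press_result(Y: pd.DataFrame, loo_resid: np.ndarray) -> PressResult:
    press = (loo_resid**2).sum(axis=0)
    n = Y.shape[0]
    y = Y.to_numpy()
    tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    cols = list(Y.columns)
    return PressResult(
        press=pd.Series(press, index=cols, name="press"),
        r2_press=pd.Series(1.0 - press / tss, index=cols, name="r2_press"),
        rmse_press=pd.Series(np.sqrt(press / n), index=cols, name="rmse_press"),
        loo_residuals=pd.DataFrame(loo_resid, index=Y.index, columns=cols),
    )


def press_loo(X, Y, include_intercept: bool = False) -> PressResult:
    """PRESS via the leverage shortcut: loo residual_i = e_i / (1 - h_ii).

    Raises
    ------
    ValueError
        If any leverage is within tolerance of 1 (the refit without that
        subject is not identified); the error names the observation.
    """
    fit = fit_multivariate_least_squares(X, Y, include_intercept=include_intercept)
    if fit.n <= fit.p + 1:
        raise ValueError(
            f"need n > p + 1 for leave-one-out validation (n={fit.n}, p={fit.p})"
        )
    h = fit.hat_diagonals.to_numpy()
    bad = np.nonzero(h >= 1 - _LEVERAGE_TOL)[0]
    if bad.size:
        labels = [str(fit.hat_diagonals.index[i]) for i in bad]
        raise ValueError(
            "leverage ~ 1 for observation(s) "
            + ", ".join(labels)
            + "; leave-one-out prediction is undefined there"
        )
    loo = fit.residuals.to_numpy() / (1.0 - h)[:, None]
    return _press_result(fit.Y, loo)


def press_naive(X, Y, include_intercept: bool = False) -> PressResult:
    """Literal delete-one refit PRESS; independent cross-check of press_loo."""
    X = _as_frame(X, "x")
    Y = _as_frame(Y, "y")
    n = X.shape[0]
    p = X.shape[1] + (1 if include_intercept else 0)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 for leave-one-out validation (n={n}, p={p})")
    loo = np.empty(Y.shape)
    for i in range(n):
        keep = np.arange(n) != i
        fit_i = fit_multivariate_least_squares(
            X.iloc[keep], Y.iloc[keep], include_intercept=include_intercept
        )
        xi = X.iloc[[i]].copy()
        if include_intercept:
            xi.insert(0, fit_i.X.columns[0], 1.0)
        pred = xi.to_numpy() @ fit_i.beta_hat.to_numpy()
        loo[i] = Y.iloc[i].to_numpy() - pred[0]
    return _press_result(Y, loo)


@dataclass
class TemResult:
    """Absolute (input units) and relative (%) technical error of measurement."""

    tem: float
    tem_pct: float
    n_pairs: int


def technical_error(pairs) -> TemResult:
    """Dahlberg technical error of measurement from duplicate pairs.

    Parameters
    ----------
    pairs : (m, 2) array-like of repeated measurements of one variable.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (m, 2) array with m >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    grand_mean = arr.mean()
    if grand_mean <= 0:
        raise ValueError("grand mean of the duplicate measurements must be positive")
    d = arr[:, 0] - arr[:, 1]
    m = arr.shape[0]
    tem = float(np.sqrt((d**2).sum() / (2 * m)))
    return TemResult(tem=tem, tem_pct=100.0 * tem / grand_mean, n_pairs=m)
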