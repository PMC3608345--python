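"""Simultaneous multivariate least squares and model development diagnostics.

The three body components are modelled jointly as Y = X B + E with Y an
n x 3 response matrix, X an n x p design (no intercept column by default,
matching the published equations) and B a p x 3 coefficient matrix.  The
least-squares B solves the normal equations (X'X) B = X'Y via the classical
inverse, which exists when X has full column rank; column-wise it is
identical to three univariate fits, but the joint formulation shares a
single design and supports multivariate hypothesis tests.

Terms are tested with Pillai's trace V = tr(H (H + E)^-1), converted to an
approximate F statistic; multicollinearity is diagnosed by the ratio of the
largest to the smallest eigenvalue of X'X (weak < 100, moderate 100-1000,
severe > 1000); and a common-predictor stepwise procedure selects variables
retained by all three responses.

R-squared follows R's convention for no-intercept fits (total sum of squares
about zero); with an intercept the usual centered total sum of squares is
used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SingularDesignError",
    "MultivariateFit",
    "PillaiTest",
    "CollinearityReport",
    "SelectionTrace",
    "fit_multivariate_least_squares",
    "pillai_trace",
    "pillai_trace_test",
    "collinearity_ratio",
    "select_common_predictors",
]

INTERCEPT_LABEL = "(intercept)"

#: Eigenvalue-ratio bands for X'X; both boundaries classify as moderate.
COLLINEARITY_BANDS = {"weak": 100.0, "moderate": 1000.0}


class SingularDesignError(ValueError):
    """The design matrix is rank deficient.

    ``dependent_columns`` names columns that are (numerically) linear
    combinations of earlier columns.
    """

    def __init__(self, dependent_columns: Sequence[str]):
        self.dependent_columns = tuple(dependent_columns)
        super().__init__(
            "design matrix is rank deficient; linearly dependent column(s): "
            + ", ".join(map(str, self.dependent_columns))
        )


def _as_frame(a, prefix: str) -> pd.DataFrame:
    if isinstance(a, pd.DataFrame):
        return a
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return pd.DataFrame(a, columns=[f"{prefix}{j}" for j in range(a.shape[1])])


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose QR pivot magnitude collapses — the rank-deficient ones."""
    arr = X.to_numpy()
    _, R = np.linalg.qr(arr)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    return [c for c, d in zip(X.columns, diag) if d < 1e-10 * scale]


@dataclass
class MultivariateFit:
    """Result of a joint least-squares fit of all responses on one design.

    Attributes
    ----------
    beta_hat : DataFrame, p x m coefficient estimates (rows follow the design
        columns, including ``(intercept)`` when fitted).
    residuals, fitted : DataFrame, n x m.
    hat_diagonals : Series of leverages h_ii; they lie in [0, 1] and sum to p.
    r2, adj_r2, see_residual : Series per response; ``see_residual`` is
        sqrt(SSE / (n - p)).
    """

    X: pd.DataFrame
    Y: pd.DataFrame
    beta_hat: pd.DataFrame
    residuals: pd.DataFrame
    fitted: pd.DataFrame
    hat_diagonals: pd.Series
    r2: pd.Series
    adj_r2: pd.Series
    see_residual: pd.Series
    include_intercept: bool

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def error_crossprod(self) -> np.ndarray:
        """E = residual cross-product matrix (m x m)."""
        r = self.residuals.to_numpy()
        return r.T @ r

    def coefficient_table(self) -> pd.DataFrame:
        """Coefficients plus per-response precision rows, in the layout of the
        published model matrix."""
        table = self.beta_hat.copy()
        table.loc["R2"] = self.r2
        table.loc["Adj_R2"] = self.adj_r2
        table.loc["SEE_residual"] = self.see_residual
        return table


def fit_multivariate_least_squares(
    X, Y, include_intercept: bool = False
) -> MultivariateFit:
    """Fit Y = X B + E by least squares through the normal equations.

    Parameters
    ----------
    X : DataFrame or array, n x p design (no intercept column; pass
        ``include_intercept=True`` to prepend one).
    Y : DataFrame or array, n x m responses.

    Raises
    ------
    SingularDesignError
        If X (with intercept, when requested) is rank deficient; the message
        names the dependent column(s).
    """
    X = _as_frame(X, "x").copy()
    Y = _as_frame(Y, "y")
    if include_intercept:
        X.insert(0, INTERCEPT_LABEL, 1.0)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations than predictors (n={n}, p={p})")
    if not np.all(np.isfinite(X.to_numpy())) or not np.all(np.isfinite(Y.to_numpy())):
        raise ValueError("design and response matrices must be finite")
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")

    arr = X.to_numpy()
    dep = _dependent_columns(X)
    if dep:
        raise SingularDesignError(dep)

    xtx = arr.T @ arr
    beta = np.linalg.solve(xtx, arr.T @ Y.to_numpy())
    fitted = arr @ beta
    resid = Y.to_numpy() - fitted

    # leverages via thin QR: h_ii = row sums of Q**2
    q, _ = np.linalg.qr(arr)
    hat = (q**2).sum(axis=1)

    sse = (resid**2).sum(axis=0)
    y = Y.to_numpy()
    if include_intercept:
        tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        adj_num, adj_den = n - 1, n - p
    else:
        tss = (y**2).sum(axis=0)  # uncentered: no-intercept convention
        adj_num, adj_den = n, n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / tss
    adj_r2 = 1.0 - (1.0 - r2) * adj_num / adj_den
    see = np.sqrt(sse / (n - p))

    cols = list(Y.columns)
    return MultivariateFit(
        X=X,
        Y=Y,
        beta_hat=pd.DataFrame(beta, index=list(X.columns), columns=cols),
        residuals=pd.DataFrame(resid, index=X.index, columns=cols),
        fitted=pd.DataFrame(fitted, index=X.index, columns=cols),
        hat_diagonals=pd.Series(hat, index=X.index, name="hat"),
        r2=pd.Series(r2, index=cols, name="r2"),
        adj_r2=pd.Series(adj_r2, index=cols, name="adj_r2"),
        see_residual=pd.Series(see, index=cols, name="see_residual"),
        include_intercept=include_intercept,
    )


@dataclass
class PillaiTest:
    """Pillai's trace test of a set of model terms.

    ``statistic`` is V = tr(H (H + E)^-1) with H the hypothesis and E the
    error cross-product matrix; 0 <= V <= s = min(m responses, h terms).
    ``f_value`` is the standard approximate F transform with
    (df_num, df_den) degrees of freedom; exact when s = 1.
    """

    statistic: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    s: int
    terms: tuple


def pillai_trace(H: np.ndarray, E: np.ndarray) -> float:
    """Trace kernel: V = tr(H (H + E)^-1)."""
    H = np.asarray(H, dtype=float)
    E = np.asarray(E, dtype=float)
    total = H + E
    scale = np.linalg.norm(total)
    if np.linalg.norm(H) <= 1e-12 * max(scale, 1.0):
        return 0.0  # no hypothesis effect, even when E is singular (noise-free)
    if np.linalg.matrix_rank(total) < total.shape[0]:
        raise np.linalg.LinAlgError("H + E is singular")
    return float(np.trace(np.linalg.solve(total.T, H.T).T))


def pillai_trace_test(fit: MultivariateFit, term_columns) -> PillaiTest:
    """Test whether the given design columns contribute to any response.

    Compares the fitted model against the model with ``term_columns``
    removed: H is the drop in the residual cross-product, E the full-model
    residual cross-product.
    """
    if isinstance(term_columns, str):
        term_columns = [term_columns]
    terms = tuple(term_columns)
    if not terms:
        raise ValueError("term_columns must not be empty")
    unknown = [t for t in terms if t not in fit.X.columns]
    if unknown:
        raise KeyError(f"terms not in design: {unknown}")

    E = fit.error_crossprod
    reduced_cols = [c for c in fit.X.columns if c not in terms]
    if reduced_cols:
        reduced = fit_multivariate_least_squares(
            fit.X[reduced_cols], fit.Y, include_intercept=False
        )
        E_reduced = reduced.error_crossprod
    else:
        y = fit.Y.to_numpy()
        E_reduced = y.T @ y
    H = E_reduced - E

    V = pillai_trace(H, E)
    m = fit.Y.shape[1]
    h = len(terms)
    nu_e = fit.n - fit.p
    s = min(m, h)
    mm = (abs(h - m) - 1) / 2.0
    nn = (nu_e - m - 1) / 2.0
    df_num = s * (2 * mm + s + 1)
    df_den = s * (2 * nn + s + 1)
    if df_den <= 0:
        raise ValueError("not enough error degrees of freedom for the Pillai test")
    # clip V into the valid open interval to keep the F transform finite
    V_c = min(max(V, 0.0), s - 1e-12)
    f_value = (df_den / df_num) * V_c / (s - V_c)
    p_value = float(stats.f.sf(f_value, df_num, df_den))
    return PillaiTest(
        statistic=V,
        f_value=float(f_value),
        df_num=float(df_num),
        df_den=float(df_den),
        p_value=p_value,
        s=s,
        terms=terms,
    )


@dataclass
class CollinearityReport:
    """Eigenvalue-ratio multicollinearity diagnostic of X'X."""

    lambda_ratio: float
    category: str
    eigenvalues: np.ndarray

    @property
    def singular(self) -> bool:
        return math.isinf(self.lambda_ratio)


def collinearity_ratio(X) -> CollinearityReport:
    """Largest / smallest eigenvalue of X'X on the raw (unscaled) design.

    Categories: weak (< 100), moderate (100 to 1000, boundaries included),
    severe (> 1000).  A smallest eigenvalue at machine tolerance yields an
    infinite ratio flagged severe.
    """
    X = _as_frame(X, "x")
    if X.size == 0:
        raise ValueError("design matrix is empty")
    arr = X.to_numpy()
    eig = np.linalg.eigvalsh(arr.T @ arr)
    largest = eig[-1]
    smallest = eig[0]
    tol = max(arr.shape) * np.finfo(float).eps * max(largest, 0.0)
    if smallest <= tol:
        return CollinearityReport(
            lambda_ratio=float("inf"), category="severe", eigenvalues=eig
        )
    ratio = float(largest / smallest)
    if ratio < COLLINEARITY_BANDS["weak"]:
        category = "weak"
    elif ratio <= COLLINEARITY_BANDS["moderate"]:
        category = "moderate"
    else:
        category = "severe"
    return CollinearityReport(lambda_ratio=ratio, category=category, eigenvalues=eig)


@dataclass
class SelectionTrace:
    """Replayable log of the common-predictor selection.

    ``steps`` is an ordered list of dicts (phase, response where applicable,
    action, variable, statistic, p-value, model at that point); ``final`` the
    retained labels; ``per_response`` the univariate stepwise results.
    """

    candidates: tuple
    steps: list
    per_response: dict
    final: tuple

    @property
    def empty(self) -> bool:
        return len(self.final) == 0


def _partial_f(X: pd.DataFrame, y: np.ndarray, full_cols, drop_col):
    """Partial F-statistic and p-value for removing one column (no intercept)."""
    n = X.shape[0]
    full = list(full_cols)
    arr_full = X[full].to_numpy()
    beta, sse_full, *_ = np.linalg.lstsq(arr_full, y, rcond=None)
    resid_full = y - arr_full @ beta
    sse_full = float(resid_full @ resid_full)
    reduced = [c for c in full if c != drop_col]
    if reduced:
        arr_red = X[reduced].to_numpy()
        beta_r, *_ = np.linalg.lstsq(arr_red, y, rcond=None)
        resid_red = y - arr_red @ beta_r
        sse_red = float(resid_red @ resid_red)
    else:
        sse_red = float(y @ y)
    df_e = n - len(full)
    if df_e <= 0 or sse_full <= 0:
        return float("inf"), 0.0
    f = (sse_red - sse_full) / (sse_full / df_e)
    return f, float(stats.f.sf(f, 1, df_e))


def _stepwise_univariate(X: pd.DataFrame, y: np.ndarray, entry_alpha, removal_alpha):
    """Forward-backward stepwise for one response, no intercept; returns
    (retained columns, step log)."""
    model: list[str] = []
    log: list[dict] = []
    changed = True
    while changed:
        changed = False
        # forward step: best candidate by entry p-value
        best = None
        for cand in X.columns:
            if cand in model:
                continue
            trial = model + [cand]
            if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
                continue
            f, p = _partial_f(X, y, trial, cand)
            if p < entry_alpha and (best is None or p < best[2]):
                best = (cand, f, p)
        if best is not None:
            model.append(best[0])
            log.append(
                {"phase": "univariate", "action": "add", "variable": best[0],
                 "F": best[1], "p": best[2], "model": tuple(model)}
            )
            changed = True
        # backward step: worst retained term by removal p-value
        while model:
            worst = None
            for col in model:
                f, p = _partial_f(X, y, model, col)
                if p > removal_alpha and (worst is None or p > worst[2]):
                    worst = (col, f, p)
            if worst is None:
                break
            model.remove(worst[0])
            log.append(
                {"phase": "univariate", "action": "remove", "variable": worst[0],
                 "F": worst[1], "p": worst[2], "model": tuple(model)}
            )
            changed = True
    return model, log


def select_common_predictors(
    X_full, Y, entry_alpha: float = 0.05, removal_alpha: float = 0.05
) -> SelectionTrace:
    """Select predictors retained by all three responses.

    Runs a per-response forward-backward stepwise (partial F tests, no
    intercept), intersects the retained sets, then prunes intersection
    members whose joint-model Pillai p-value exceeds ``removal_alpha``
    provided their removal keeps the collinearity category at most moderate.
    An empty intersection yields an empty (non-exceptional) selection.
    """
    X_full = _as_frame(X_full, "x")
    Y = _as_frame(Y, "y")
    if X_full.shape[1] < 2:
        raise ValueError("need at least 2 candidate columns")
    if not 0 < entry_alpha < 1 or not 0 < removal_alpha < 1:
        raise ValueError("alphas must lie in (0, 1)")

    steps: list[dict] = []
    per_response: dict[str, tuple] = {}
    for col in Y.columns:
        retained, log = _stepwise_univariate(
            X_full, Y[col].to_numpy(), entry_alpha, removal_alpha
        )
        for entry in log:
            entry = dict(entry)
            entry["response"] = col
            steps.append(entry)
        per_response[col] = tuple(retained)

    common = [
        c for c in X_full.columns
        if all(c in per_response[r] for r in Y.columns)
    ]
    steps.append(
        {"phase": "intersection", "action": "intersect", "model": tuple(common)}
    )

    # joint pruning with Pillai tests
    changed = True
    while changed and len(common) > 1:
        changed = False
        fit = fit_multivariate_least_squares(X_full[common], Y)
        tests = {c: pillai_trace_test(fit, [c]) for c in common}
        removable = sorted(
            (c for c in common if tests[c].p_value > removal_alpha),
            key=lambda c: -tests[c].p_value,
        )
        for col in removable:
            remaining = [c for c in common if c != col]
            report = collinearity_ratio(X_full[remaining])
            if report.category in ("weak", "moderate"):
                common = remaining
                steps.append(
                    {"phase": "joint", "action": "remove", "variable": col,
                     "F": tests[col].f_value, "p": tests[col].p_value,
                     "model": tuple(common)}
                )
                changed = True
                break

    return SelectionTrace(
        candidates=tuple(X_full.columns),
        steps=steps,
        per_response=per_response,
        final=tuple(common),
    )
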