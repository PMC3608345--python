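"""Synthetic cohorts with the statistical structure of the development sample.

No individual-level data is deposited with the published model, so the
package generates cohorts that reproduce the development sample's printed
summary statistics: per-variable means, SDs and observed ranges, and the
printed pairwise correlations between the anthropometric predictors, age,
maturity offset and the three body components.

Generation uses a Gaussian copula with truncated-normal marginals.  For each
variable the underlying normal (mu, sigma) is calibrated so the *truncated*
distribution has exactly the target mean and an SD as close as feasible to
the target (truncating a normal to the observed range would otherwise bias
skewed variables such as fat mass by ~20%).  Joint structure comes from a
correlation matrix assembled from the printed entries, completed by
documented rules for the unprinted pairs, and repaired to the nearest
positive semi-definite correlation matrix.

Model-driven cohorts draw only the five predictors and construct responses
as X @ beta + Gaussian noise, enabling parameter-recovery and validation
experiments against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.correlation_tools import corr_nearest

from .core import (
    PREDICTORS,
    RESPONSES,
    AnthropometricRecord,
    CoefficientMatrix,
    _mirwald,
    published_coefficients,
)

__all__ = [
    "VARIABLES",
    "PopulationMoments",
    "SyntheticCohort",
    "default_moments",
    "generate_cohort",
    "generate_from_coefficients",
    "generate_duplicates",
    "cohort_summary",
]

#: Canonical variable order of the modeled set.
VARIABLES = (
    "height", "weight", "seating_height", "age", "phv",
    "sk_suprailiac", "sk_horiz_abdominal", "fm", "bmc", "lst",
)

# Printed per-variable summary statistics of the development sample
# (n = 408 boys, 8-18 y): mean, SD, observed (min, max).
_TABLE_MOMENTS = {
    "height": (158.1, 17.7, 120.3, 196.8),
    "weight": (50.2, 17.4, 20.6, 119.4),
    "seating_height": (82.3, 8.8, 61.5, 99.5),
    "age": (13.7, 2.99, 8.0, 18.0),
    "phv": (-0.5, 2.5, -4.7, 4.5),
    "sk_suprailiac": (13.3, 10.2, 2.8, 64.5),
    "sk_horiz_abdominal": (16.5, 12.0, 1.5, 66.0),
    "fm": (9.3, 7.5, 1.3, 41.8),
    "bmc": (2.1, 0.8, 0.7, 4.1),
    "lst": (38.1, 12.7, 17.1, 72.6),
}

# Printed pairwise correlations over the modeled subset.
_PRINTED_CORRELATIONS = {
    ("height", "weight"): 0.84,
    ("height", "sk_suprailiac"): 0.12,
    ("height", "sk_horiz_abdominal"): 0.11,
    ("height", "phv"): 0.94,
    ("height", "age"): 0.88,
    ("height", "fm"): 0.28,
    ("height", "bmc"): 0.91,
    ("height", "lst"): 0.95,
    ("weight", "sk_suprailiac"): 0.54,
    ("weight", "sk_horiz_abdominal"): 0.52,
    ("weight", "phv"): 0.87,
    ("weight", "age"): 0.78,
    ("weight", "fm"): 0.70,
    ("weight", "bmc"): 0.92,
    ("weight", "lst"): 0.91,
    ("sk_suprailiac", "sk_horiz_abdominal"): 0.90,
    ("sk_suprailiac", "phv"): 0.17,
    ("sk_suprailiac", "age"): 0.08,
    ("sk_suprailiac", "fm"): 0.92,
    ("sk_suprailiac", "bmc"): 0.24,
    ("sk_suprailiac", "lst"): 0.17,
    ("sk_horiz_abdominal", "phv"): 0.15,
    ("sk_horiz_abdominal", "age"): 0.05,
    ("sk_horiz_abdominal", "fm"): 0.92,
    ("sk_horiz_abdominal", "bmc"): 0.22,
    ("sk_horiz_abdominal", "lst"): 0.14,
    ("phv", "age"): 0.97,
    ("phv", "fm"): 0.32,
    ("phv", "bmc"): 0.93,
    ("phv", "lst"): 0.95,
    ("age", "fm"): 0.22,
    ("age", "bmc"): 0.87,
    ("age", "lst"): 0.89,
}

#: Residual SDs of the published fit, kg (FM, BMC, LST); used both as default
#: noise for model-driven cohorts and in the response-correlation completion.
PUBLISHED_NOISE_SD = (1.6660, 0.1923, 1.7480)

# Sitting height has no printed correlations; it is anchored to stature at
# this value and routed through stature for every other pair.
_SEATING_HEIGHT_ANCHOR = 0.95


@dataclass
class PopulationMoments:
    """Per-variable moments and the pairwise correlation matrix.

    ``correlation`` holds the printed/imputed target values exactly;
    :meth:`psd_correlation` returns the nearest positive semi-definite repair
    actually used for generation (the repair moves entries by < 0.005 for the
    default moments).
    """

    means: pd.Series
    sds: pd.Series
    ranges: pd.DataFrame  # columns: min, max
    correlation: pd.DataFrame
    _psd_cache: np.ndarray | None = field(default=None, repr=False, compare=False)
    _latent_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        vars_ = list(self.means.index)
        corr = self.correlation
        if list(corr.index) != vars_ or list(corr.columns) != vars_:
            raise ValueError("correlation matrix labels must match the variables")
        arr = corr.to_numpy()
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if (self.sds <= 0).any():
            raise ValueError("SDs must be positive")
        if (self.ranges["min"] >= self.ranges["max"]).any():
            raise ValueError("ranges must satisfy min < max")

    @property
    def variables(self) -> tuple:
        return tuple(self.means.index)

    def psd_correlation(self) -> np.ndarray:
        """Nearest positive semi-definite repair of ``correlation``."""
        if self._psd_cache is None:
            arr = self.correlation.to_numpy()
            if np.linalg.eigvalsh(arr).min() >= 1e-8:
                repaired = arr
            else:
                with warnings.catch_warnings():
                    # convergence is verified below on the eigenvalues instead
                    warnings.simplefilter("ignore")
                    repaired = corr_nearest(arr, threshold=1e-7, n_fact=500)
            if np.linalg.eigvalsh(repaired).min() < -1e-10:
                raise ValueError("correlation matrix could not be repaired to PSD")
            self._psd_cache = repaired
        return self._psd_cache

    def subset(self, variables) -> "PopulationMoments":
        """Moments restricted to a subset of variables (PSD is preserved)."""
        variables = list(variables)
        sub = PopulationMoments(
            means=self.means[variables],
            sds=self.sds[variables],
            ranges=self.ranges.loc[variables],
            correlation=self.correlation.loc[variables, variables],
        )
        if self._psd_cache is not None:
            idx = [list(self.means.index).index(v) for v in variables]
            sub._psd_cache = self._psd_cache[np.ix_(idx, idx)]
        return sub


def default_moments() -> PopulationMoments:
    """Moments of the development sample, with unprinted correlations imputed.

    Completion rules (documented in the methods note):

    * response-response pairs (FM/BMC/LST) use the correlations implied by
      the published model, cov(Y) = B' Sigma_x B + diag(SEE^2), with Sigma_x
      from the printed predictor SDs and correlations;
    * sitting height is anchored to stature at 0.95 and every other pair is
      routed through stature, r(Sh, v) = 0.95 * r(Ht, v).

    The matrix is then repaired to the nearest PSD correlation matrix for
    generation; printed entries move by less than 0.005.
    """
    vars_ = list(VARIABLES)
    k = len(vars_)
    corr = pd.DataFrame(np.eye(k), index=vars_, columns=vars_)
    for (a, b), v in _PRINTED_CORRELATIONS.items():
        corr.loc[a, b] = corr.loc[b, a] = v

    # response-response completion via the published model
    beta = published_coefficients().values
    pred_sds = np.array([_TABLE_MOMENTS[v][1] for v in PREDICTORS])
    pred_corr = corr.loc[list(PREDICTORS), list(PREDICTORS)].to_numpy()
    sigma_x = np.outer(pred_sds, pred_sds) * pred_corr
    sigma_y = beta.T @ sigma_x @ beta + np.diag(np.array(PUBLISHED_NOISE_SD) ** 2)
    d = np.sqrt(np.diag(sigma_y))
    corr_y = sigma_y / np.outer(d, d)
    for i, a in enumerate(RESPONSES):
        for j, b in enumerate(RESPONSES):
            if i < j:
                corr.loc[a, b] = corr.loc[b, a] = round(float(corr_y[i, j]), 4)

    # sitting height routed through stature
    corr.loc["seating_height", "height"] = _SEATING_HEIGHT_ANCHOR
    corr.loc["height", "seating_height"] = _SEATING_HEIGHT_ANCHOR
    for v in vars_:
        if v in ("height", "seating_height"):
            continue
        val = round(_SEATING_HEIGHT_ANCHOR * float(corr.loc["height", v]), 4)
        corr.loc["seating_height", v] = corr.loc[v, "seating_height"] = val

    means = pd.Series({v: _TABLE_MOMENTS[v][0] for v in vars_})
    sds = pd.Series({v: _TABLE_MOMENTS[v][1] for v in vars_})
    ranges = pd.DataFrame(
        {"min": {v: _TABLE_MOMENTS[v][2] for v in vars_},
         "max": {v: _TABLE_MOMENTS[v][3] for v in vars_}}
    ).loc[vars_]
    return PopulationMoments(means=means, sds=sds, ranges=ranges, correlation=corr)


@lru_cache(maxsize=256)
def _calibrate_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Underlying normal (mu, sigma) whose truncation to [lo, hi] has the
    target mean exactly and an SD as close as feasible to the target.

    Some printed SDs are infeasible for any truncated normal on the printed
    range (the maximum is (hi-lo)/sqrt(12), approached in the flat limit); in
    that case the closest achievable SD is used.
    """
    if not lo < mean < hi:
        raise ValueError(f"target mean {mean} must lie inside ({lo}, {hi})")

    def trunc_stats(mu, sig):
        a, b = (lo - mu) / sig, (hi - mu) / sig
        return (
            stats.truncnorm.mean(a, b, loc=mu, scale=sig),
            stats.truncnorm.std(a, b, loc=mu, scale=sig),
        )

    def mu_for(sig):
        # truncated mean is increasing in mu
        f = lambda mu: trunc_stats(mu, sig)[0] - mean
        return optimize.brentq(f, lo - 60 * sig, hi + 60 * sig, xtol=1e-12 * max(1.0, abs(mean)))

    def sd_gap(log_sig):
        sig = float(np.exp(log_sig))
        try:
            mu = mu_for(sig)
        except ValueError:
            return 1e12
        return (trunc_stats(mu, sig)[1] - sd) ** 2

    res = optimize.minimize_scalar(
        sd_gap,
        bounds=(np.log(max(sd / 10.0, 1e-6)), np.log(10.0 * (hi - lo))),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sigma = float(np.exp(res.x))
    mu = float(mu_for(sigma))
    return mu, sigma


_GH_ORDER = 32


@lru_cache(maxsize=1)
def _gauss_hermite():
    # probabilists' nodes/weights for E[f(Z)], Z ~ N(0,1)
    t, w = np.polynomial.hermite_e.hermegauss(_GH_ORDER)
    return t, w / w.sum()


def _truncnorm_at(z: np.ndarray, marg) -> np.ndarray:
    mu, sigma, lo, hi = marg
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    u = np.clip(stats.norm.cdf(z), np.finfo(float).tiny, 1 - 1e-16)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


@lru_cache(maxsize=512)
def _node_moments(marg):
    t, w = _gauss_hermite()
    g = _truncnorm_at(t, marg)
    mean = float(w @ g)
    sd = float(np.sqrt(w @ (g - mean) ** 2))
    return g, mean, sd


@lru_cache(maxsize=8192)
def _latent_rho(marg_i, marg_j, target: float) -> float:
    """Gaussian-copula correlation inducing the target Pearson correlation
    between two truncated-normal marginals.

    The marginal transforms are monotone but nonlinear, so the induced
    Pearson correlation is attenuated relative to the latent one; this solves
    the inverse problem by Gauss-Hermite quadrature.  If the target exceeds
    the maximum attainable correlation for the two marginal shapes, the
    latent correlation is clamped near +/-1 (closest attainable).
    """
    if abs(target) < 1e-12:
        return 0.0
    t, w = _gauss_hermite()
    g_i, m_i, s_i = _node_moments(marg_i)
    _, m_j, s_j = _node_moments(marg_j)

    def induced(rho):
        z2 = rho * t[:, None] + np.sqrt(1.0 - rho * rho) * t[None, :]
        g_j = _truncnorm_at(z2, marg_j)
        e_xy = float(w @ (g_i[:, None] * g_j) @ w)
        return (e_xy - m_i * m_j) / (s_i * s_j)

    lo, hi = (0.0, 0.99995) if target > 0 else (-0.99995, 0.0)
    f_hi = induced(hi if target > 0 else lo)
    if target > 0 and f_hi <= target:
        return hi
    if target < 0 and f_hi >= target:
        return lo
    return float(optimize.brentq(lambda r: induced(r) - target, lo, hi, xtol=1e-7))


def _latent_correlation(moments: "PopulationMoments") -> np.ndarray:
    """Latent (copula) correlation matrix whose induced Pearson correlations
    match the target matrix, repaired to PSD."""
    vars_ = list(moments.variables)
    target = moments.psd_correlation()
    margs = [
        _calibrate_truncnorm(
            float(moments.means[v]),
            float(moments.sds[v]),
            float(moments.ranges.loc[v, "min"]),
            float(moments.ranges.loc[v, "max"]),
        )
        + (
            float(moments.ranges.loc[v, "min"]),
            float(moments.ranges.loc[v, "max"]),
        )
        for v in vars_
    ]
    k = len(vars_)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            latent[i, j] = latent[j, i] = _latent_rho(
                margs[i], margs[j], float(target[i, j])
            )
    if np.linalg.eigvalsh(latent).min() < 1e-8:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            latent = corr_nearest(latent, threshold=1e-7, n_fact=500)
    return latent


def _lognormal_params(mean: float, sd: float):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _marginal_ppf(u: np.ndarray, variable: str, moments: PopulationMoments,
                  skinfold_marginal: str) -> np.ndarray:
    mean = float(moments.means[variable])
    sd = float(moments.sds[variable])
    lo, hi = (float(moments.ranges.loc[variable, "min"]),
              float(moments.ranges.loc[variable, "max"]))
    if skinfold_marginal == "lognormal" and variable.startswith("sk_"):
        mu, s = _lognormal_params(mean, sd)
        dist = stats.lognorm(s=s, scale=np.exp(mu))
        plo, phi = dist.cdf(lo), dist.cdf(hi)
        return dist.ppf(plo + u * (phi - plo))
    mu, sigma = _calibrate_truncnorm(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _copula_sample(n: int, moments: PopulationMoments, rng: np.random.Generator,
                   skinfold_marginal: str = "truncnorm") -> pd.DataFrame:
    vars_ = list(moments.variables)
    if skinfold_marginal == "truncnorm":
        # latent matrix adjusted so induced Pearson correlations hit targets
        if moments._latent_cache is None:
            moments._latent_cache = _latent_correlation(moments)
        R = moments._latent_cache
    else:
        R = moments.psd_correlation()
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(vars_)))
    z = rng.standard_normal((n, len(vars_))) @ L.T
    u = stats.norm.cdf(z)
    # keep u strictly inside (0, 1) for the ppf transforms
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1 - 1e-16)
    data = {
        v: _marginal_ppf(u[:, j], v, moments, skinfold_marginal)
        for j, v in enumerate(vars_)
    }
    return pd.DataFrame(data, columns=vars_)


@dataclass
class SyntheticCohort:
    """A generated cohort: one row per subject, measurements plus responses.

    ``provenance`` is ``"moments-driven"`` (all variables drawn jointly from
    the population moments) or ``"model-driven"`` (predictors drawn, responses
    constructed from a known coefficient matrix plus noise).
    """

    data: pd.DataFrame
    seed: int | None
    provenance: str

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def predictors(self) -> pd.DataFrame:
        return self.data[list(PREDICTORS)]

    def responses(self) -> pd.DataFrame:
        return self.data[list(RESPONSES)]

    def records(self) -> list[AnthropometricRecord]:
        fields = [
            "height", "weight", "sk_suprailiac", "sk_horiz_abdominal",
            "seating_height", "age", "phv",
        ]
        out = []
        for _, row in self.data.iterrows():
            kwargs = {f: float(row[f]) for f in fields if f in row.index}
            out.append(AnthropometricRecord(**kwargs))
        return out


def generate_cohort(
    n: int,
    moments: PopulationMoments | None = None,
    seed: int | None = None,
    skinfold_marginal: str = "truncnorm",
    phv_from_equation: bool = False,
) -> SyntheticCohort:
    """Draw a moments-driven cohort of ``n`` subjects.

    All variables (anthropometrics, age, maturity offset and the three body
    components) are drawn jointly; every value lies within the configured
    ranges and the output is a pure function of the arguments and seed.

    Parameters
    ----------
    skinfold_marginal : "truncnorm" (default) or "lognormal"; the latter uses
        range-truncated lognormal skinfold marginals (moments then match the
        targets only approximately).
    phv_from_equation : if True, the maturity-offset column is recomputed
        from age, stature, sitting height and weight with the Mirwald
        equation instead of being drawn jointly.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if skinfold_marginal not in ("truncnorm", "lognormal"):
        raise ValueError("skinfold_marginal must be 'truncnorm' or 'lognormal'")
    if moments is None:
        moments = default_moments()
    rng = np.random.default_rng(seed)
    data = _copula_sample(n, moments, rng, skinfold_marginal)
    if phv_from_equation:
        data["phv"] = _mirwald(
            data["age"], data["height"], data["seating_height"], data["weight"]
        )
    return SyntheticCohort(data=data, seed=seed, provenance="moments-driven")


def generate_from_coefficients(
    n: int,
    beta: CoefficientMatrix | None = None,
    noise_sd=PUBLISHED_NOISE_SD,
    moments: PopulationMoments | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Model-driven cohort: predictors from the population moments, responses
    X @ beta + Gaussian noise with the given per-response SDs."""
    if n <= 5:
        raise ValueError("n must exceed the number of predictors (5)")
    if beta is None:
        beta = published_coefficients()
    noise_sd = np.asarray(noise_sd, dtype=float)
    if noise_sd.shape != (len(beta.response_labels),):
        raise ValueError(
            f"noise_sd must have one entry per response ({len(beta.response_labels)})"
        )
    if np.any(noise_sd < 0):
        raise ValueError("noise SDs must be non-negative")
    if moments is None:
        moments = default_moments()
    pred_moments = moments.subset(beta.predictor_labels)
    rng = np.random.default_rng(seed)
    X = _copula_sample(n, pred_moments, rng)
    noise = rng.standard_normal((n, len(beta.response_labels))) * noise_sd
    Y = X.to_numpy() @ beta.values + noise
    data = X.copy()
    for j, resp in enumerate(beta.response_labels):
        data[resp] = Y[:, j]
    return SyntheticCohort(data=data, seed=seed, provenance="model-driven")


def generate_duplicates(
    cohort: SyntheticCohort,
    tem_targets: Mapping[str, float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated duplicate measurements for technical-error studies.

    The second measurement is the first plus Gaussian error with
    SD = tem * sqrt(2), so the expected Dahlberg TEM equals the target.
    Returns a long-format table (subject, variable, measurement_1,
    measurement_2).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for variable, tem in tem_targets.items():
        if tem < 0:
            raise ValueError(f"TEM target for {variable} must be >= 0, got {tem}")
        if variable not in cohort.data.columns:
            raise KeyError(f"variable {variable!r} not in cohort")
        first = cohort.data[variable].to_numpy()
        second = first + rng.standard_normal(first.shape) * (tem * np.sqrt(2.0))
        for i, (m1, m2) in enumerate(zip(first, second)):
            rows.append(
                {"subject": i, "variable": variable,
                 "measurement_1": m1, "measurement_2": m2}
            )
    return pd.DataFrame(rows)


def cohort_summary(cohort: SyntheticCohort) -> PopulationMoments:
    """Sample moments of a cohort, in the same layout as the targets.

    Constant columns are reported with SD 0 and undefined (NaN) correlations.
    """
    df = cohort.data
    if df.shape[0] < 2:
        raise ValueError("need at least 2 rows to summarize a cohort")
    means = df.mean()
    sds = df.std(ddof=1)
    ranges = pd.DataFrame({"min": df.min(), "max": df.max()})
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = df.corr()
    np.fill_diagonal(corr.to_numpy(), 1.0)
    # bypass validation for degenerate summaries (SD 0 allowed here)
    obj = PopulationMoments.__new__(PopulationMoments)
    obj.means = means
    obj.sds = sds
    obj.ranges = ranges
    obj.correlation = corr
    obj._psd_cache = None
    obj._latent_cache = None
    return obj
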