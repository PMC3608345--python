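"""Domain types and the published multicomponent body-composition predictor.

The model predicts fat mass (FM), bone mineral content (BMC) and lean soft
tissue (LST), all in kg, for boys aged 8-18 from five anthropometric inputs:
stature (cm), body mass (kg), suprailiac and horizontal-abdominal skinfolds
(mm) and maturity offset (years from peak height velocity, PHV).  Each
component is an intercept-free inner product of the five measurements with a
published 5x3 coefficient matrix; the three components are estimated
simultaneously, so a single measurement vector yields all three masses.

Maturity offset is computed, when not measured, with the Mirwald boys'
equation from age, stature, sitting height and body mass.

Weight here is scale-measured body mass, not a DXA-derived total: the
prediction equation is meant for field settings where only a scale is
available.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTORS",
    "RESPONSES",
    "REFERENCE_RANGES",
    "InputDomainError",
    "MissingFieldsError",
    "ExtrapolationWarning",
    "AnthropometricRecord",
    "BodyComposition",
    "CoefficientMatrix",
    "ProductTable",
    "compute_maturity_offset",
    "published_coefficients",
    "load_coefficients",
    "predict_components",
    "product_breakdown",
]

#: Predictor order of the published model (fixed; units cm, kg, mm, mm, years).
PREDICTORS = ("height", "weight", "sk_suprailiac", "sk_horiz_abdominal", "phv")

#: Response order (kg).
RESPONSES = ("fm", "bmc", "lst")

#: Observed ranges of the development sample.  Inputs outside these ranges are
#: extrapolations: predictions are still returned but a warning is emitted.
REFERENCE_RANGES = {
    "height": (120.3, 196.8),
    "weight": (20.6, 119.4),
    "seating_height": (61.5, 99.5),
    "age": (8.0, 18.0),
    "phv": (-4.7, 4.5),
    "sk_suprailiac": (2.8, 64.5),
    "sk_horiz_abdominal": (1.5, 66.0),
}


class InputDomainError(ValueError):
    """A measurement is outside the mathematical domain of an operation."""


class MissingFieldsError(ValueError):
    """A prediction was requested from a record lacking required fields."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"missing required fields: {', '.join(self.missing)}")


class ExtrapolationWarning(UserWarning):
    """Inputs fall outside the development sample's observed ranges."""


# Mirwald maturity-offset equation for boys.  Lh is leg length
# (stature - sitting height); the last term is 100 * weight / height.
_MIRWALD_INTERCEPT = -9.236
_MIRWALD_LH_SH = 0.0002708
_MIRWALD_A_LH = -0.001663
_MIRWALD_A_SH = 0.007216
_MIRWALD_WT_HT = 0.02292


def _mirwald(age, height, seating_height, weight):
    """Vectorized Mirwald polynomial; no input validation."""
    lh = np.asarray(height) - np.asarray(seating_height)
    sh = np.asarray(seating_height)
    a = np.asarray(age)
    return (
        _MIRWALD_INTERCEPT
        + _MIRWALD_LH_SH * lh * sh
        + _MIRWALD_A_LH * a * lh
        + _MIRWALD_A_SH * a * sh
        + _MIRWALD_WT_HT * (np.asarray(weight) / np.asarray(height) * 100.0)
    )


def compute_maturity_offset(
    age: float, height: float, seating_height: float, weight: float
) -> float:
    """Years from peak height velocity (negative = pre-PHV) for a boy.

    Parameters
    ----------
    age : decimal years
    height : stature, cm
    seating_height : sitting height, cm
    weight : body mass, kg

    Returns
    -------
    float
        Predicted maturity offset in years.
    """
    for name, value in (
        ("age", age),
        ("height", height),
        ("seating_height", seating_height),
        ("weight", weight),
    ):
        if not math.isfinite(value):
            raise InputDomainError(f"{name} must be finite, got {value!r}")
    if height <= 0:
        raise InputDomainError(f"height must be positive, got {height}")
    if seating_height < 0:
        raise InputDomainError(
            f"seating_height must be non-negative, got {seating_height}"
        )
    if seating_height >= height:
        raise InputDomainError(
            f"seating_height ({seating_height}) must be smaller than height ({height})"
        )
    return float(_mirwald(age, height, seating_height, weight))


@dataclass
class AnthropometricRecord:
    """One subject's measured inputs.

    Units are fixed: cm for heights, kg for weight, mm for skinfolds, decimal
    years for age and maturity offset.  ``phv`` may be given directly or left
    ``None``, in which case it is computed from age, height, seating height
    and weight when those are available.
    """

    height: float
    weight: float
    sk_suprailiac: float
    sk_horiz_abdominal: float
    seating_height: float | None = None
    age: float | None = None
    phv: float | None = None

    def __post_init__(self):
        if not (self.height > 0):
            raise InputDomainError(f"height must be > 0, got {self.height}")
        if not (self.weight > 0):
            raise InputDomainError(f"weight must be > 0, got {self.weight}")
        for name in ("sk_suprailiac", "sk_horiz_abdominal"):
            if getattr(self, name) < 0:
                raise InputDomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.seating_height is not None and self.seating_height >= self.height:
            raise InputDomainError(
                f"seating_height ({self.seating_height}) must be smaller than "
                f"height ({self.height})"
            )

    def maturity_offset(self) -> float:
        """PHV years: the stored value, or the Mirwald estimate if absent."""
        if self.phv is not None:
            return float(self.phv)
        missing = [
            name
            for name in ("age", "seating_height")
            if getattr(self, name) is None
        ]
        if missing:
            raise MissingFieldsError(["phv"] + missing)
        return compute_maturity_offset(
            self.age, self.height, self.seating_height, self.weight
        )

    def predictor_vector(self) -> np.ndarray:
        """Model inputs in canonical order (height, weight, SkSi, SkHab, PHV)."""
        return np.array(
            [
                self.height,
                self.weight,
                self.sk_suprailiac,
                self.sk_horiz_abdominal,
                self.maturity_offset(),
            ]
        )


@dataclass
class BodyComposition:
    """The three predicted body components, kg.

    Values are finite but not sign-constrained: the intercept-free linear map
    can produce negative masses on out-of-range inputs; such predictions are
    returned as-is with an :class:`ExtrapolationWarning`, never clipped.
    """

    fm: float
    bmc: float
    lst: float

    def __post_init__(self):
        for name in RESPONSES:
            if not math.isfinite(getattr(self, name)):
                raise InputDomainError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.fm, self.bmc, self.lst])


@dataclass(frozen=True)
class CoefficientMatrix:
    """A 5 predictors x 3 responses coefficient matrix with labels."""

    values: np.ndarray
    predictor_labels: tuple = PREDICTORS
    response_labels: tuple = RESPONSES

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.predictor_labels), len(self.response_labels)):
            raise ValueError(
                f"coefficient matrix must be "
                f"{len(self.predictor_labels)}x{len(self.response_labels)}, "
                f"got {values.shape}"
            )
        if len(set(self.predictor_labels)) != len(self.predictor_labels):
            raise ValueError("predictor labels must be unique")
        if len(set(self.response_labels)) != len(self.response_labels):
            raise ValueError("response labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("coefficients must be finite")

    def __getitem__(self, key):
        predictor, response = key
        i = self.predictor_labels.index(predictor)
        j = self.response_labels.index(response)
        return float(self.values[i, j])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.predictor_labels),
            columns=list(self.response_labels),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CoefficientMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            predictor_labels=tuple(frame.index),
            response_labels=tuple(frame.columns),
        )

    def to_csv(self, path) -> None:
        frame = self.as_frame()
        frame.index.name = "predictor"
        frame.to_csv(path)


def load_coefficients(path) -> CoefficientMatrix:
    """Load a coefficient matrix from delimited text (same shape as the
    packaged resource: a ``predictor`` column then one column per response)."""
    frame = pd.read_csv(path, index_col="predictor")
    return CoefficientMatrix.from_frame(frame)


_PUBLISHED: CoefficientMatrix | None = None


def published_coefficients() -> CoefficientMatrix:
    """The published 5x3 coefficient matrix of the multicomponent model."""
    global _PUBLISHED
    if _PUBLISHED is None:
        with resources.files("anthrocomp.data").joinpath(
            "multicomponent_coefficients.csv"
        ).open("r") as fh:
            _PUBLISHED = load_coefficients(fh)
    return _PUBLISHED


def _check_extrapolation(record: AnthropometricRecord, phv: float) -> None:
    out = []
    checks = {
        "height": record.height,
        "weight": record.weight,
        "sk_suprailiac": record.sk_suprailiac,
        "sk_horiz_abdominal": record.sk_horiz_abdominal,
        "phv": phv,
    }
    for name, value in checks.items():
        lo, hi = REFERENCE_RANGES[name]
        if not (lo <= value <= hi):
            out.append(f"{name}={value:g} outside [{lo:g}, {hi:g}]")
    if out:
        warnings.warn(
            "inputs outside the development sample ranges (extrapolation): "
            + "; ".join(out),
            ExtrapolationWarning,
            stacklevel=3,
        )


def predict_components(
    record: AnthropometricRecord, coeffs: CoefficientMatrix | None = None
) -> BodyComposition:
    """Predict FM, BMC and LST (kg) for one subject.

    Each component is the inner product of (height, weight, sk_suprailiac,
    sk_horiz_abdominal, phv) with the corresponding coefficient column; the
    model has no intercept.  Negative outputs are possible for out-of-range
    inputs and are returned as-is with a warning.
    """
    if coeffs is None:
        coeffs = published_coefficients()
    phv = record.maturity_offset()
    _check_extrapolation(record, phv)
    x = np.array(
        [record.height, record.weight, record.sk_suprailiac,
         record.sk_horiz_abdominal, phv]
    )
    y = x @ coeffs.values
    if np.any(y < 0):
        neg = [r for r, v in zip(coeffs.response_labels, y) if v < 0]
        warnings.warn(
            f"negative predicted mass for {', '.join(neg)}; inputs are likely "
            "outside the model's intended range",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return BodyComposition(**dict(zip(coeffs.response_labels, map(float, y))))


@dataclass
class ProductTable:
    """Per-term contribution breakdown of one prediction.

    ``table`` has one row per predictor with the measured value, the
    coefficient for each response, and their product (kg); ``totals`` holds
    the per-response column sums, which equal the model predictions.
    """

    table: pd.DataFrame
    totals: pd.Series

    def __post_init__(self):
        sums = self.table[[f"product_{r}" for r in self.totals.index]].sum()
        sums.index = self.totals.index
        if not np.allclose(sums.to_numpy(), self.totals.to_numpy(), atol=1e-9):
            raise ValueError("totals must equal the column sums of the products")


def product_breakdown(
    record: AnthropometricRecord, coeffs: CoefficientMatrix | None = None
) -> ProductTable:
    """Decompose a prediction into one (measurement x coefficient) product
    per predictor and response, plus the per-response totals."""
    if coeffs is None:
        coeffs = published_coefficients()
    phv = record.maturity_offset()
    _check_extrapolation(record, phv)
    x = np.array(
        [record.height, record.weight, record.sk_suprailiac,
         record.sk_horiz_abdominal, phv]
    )
    products = x[:, None] * coeffs.values
    data = {"value": x}
    for j, resp in enumerate(coeffs.response_labels):
        data[f"beta_{resp}"] = coeffs.values[:, j]
        data[f"product_{resp}"] = products[:, j]
    table = pd.DataFrame(data, index=list(coeffs.predictor_labels))
    totals = pd.Series(products.sum(axis=0), index=list(coeffs.response_labels))
    return ProductTable(table=table, totals=totals)
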