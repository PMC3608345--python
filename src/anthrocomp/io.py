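"""Delimited-text I/O, run configuration and report writers.

Cohort and measurement files are plain delimited text (comma by default, tab
accepted) with a header row of canonical variable names and an optional
commented header dictionary (``# name: unit``) documenting units.  Decimal
separator is always the dot.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import PREDICTORS, RESPONSES
from .fitting import CollinearityReport, MultivariateFit
from .validation import PressResult

__all__ = [
    "VARIABLE_UNITS",
    "RunConfig",
    "read_table",
    "write_cohort",
    "read_cohort",
    "write_fit_report",
    "write_validation_report",
]

logger = logging.getLogger("anthrocomp")

VARIABLE_UNITS = {
    "height": "cm",
    "weight": "kg",
    "seating_height": "cm",
    "age": "years",
    "phv": "years",
    "sk_suprailiac": "mm",
    "sk_horiz_abdominal": "mm",
    "fm": "kg",
    "bmc": "kg",
    "lst": "kg",
}


@dataclass
class RunConfig:
    """Shared pipeline settings for the command-line entry points."""

    seed: int = 0
    entry_alpha: float = 0.05
    removal_alpha: float = 0.05
    include_intercept: bool = False
    leverage_tolerance: float = 1e-8
    log_level: str = "INFO"

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError(f"seed must be a non-negative integer, got {self.seed!r}")
        for name in ("entry_alpha", "removal_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return ","


def read_table(path) -> pd.DataFrame:
    """Read a delimited-text table, skipping ``#`` comment lines; the
    delimiter (comma or tab) is sniffed from the first data line."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value in column {col!r} at row index {bad[0]}"
                )
            df[col] = coerced
    return df


def write_cohort(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort with a commented header dictionary of units."""
    path = Path(path)
    with open(path, "w") as fh:
        for col in df.columns:
            unit = VARIABLE_UNITS.get(col, "unknown")
            fh.write(f"# {col}: {unit}\n")
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(fh, sep=sep, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    return read_table(path)


def require_columns(df: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KeyError(f"missing required column(s): {', '.join(missing)}")


def write_fit_report(
    fit: MultivariateFit,
    path,
    collinearity: CollinearityReport | None = None,
    sep: str = ",",
) -> None:
    """Coefficients plus precision statistics, one block mirroring the
    published model-matrix layout, as delimited text."""
    table = fit.coefficient_table()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# multicomponent fit report\n")
        fh.write(f"# n: {fit.n}\n# p: {fit.p}\n")
        fh.write(f"# intercept: {fit.include_intercept}\n")
        if collinearity is not None:
            fh.write(
                f"# eigenvalue_ratio: {collinearity.lambda_ratio:.4f}"
                f" ({collinearity.category})\n"
            )
        table.index.name = "term"
        table.to_csv(fh, sep=sep)


def write_validation_report(result: PressResult, path, sep: str = ",") -> None:
    """PRESS block (PRESS, R2_PRESS, rmse_press per response) plus a
    machine-readable key-value section."""
    block = pd.DataFrame(
        {"press": result.press, "r2_press": result.r2_press,
         "rmse_press": result.rmse_press}
    ).T
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# leave-one-out cross-validation report\n")
        block.index.name = "statistic"
        block.to_csv(fh, sep=sep)
        fh.write("#\n")
        for stat in ("press", "r2_press", "rmse_press"):
            for resp in result.press.index:
                value = getattr(result, stat)[resp]
                fh.write(f"# {stat}.{resp} = {value:.6f}\n")
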