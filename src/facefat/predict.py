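"""Predict body-fat parameters, chiefly BMI and PBF, from the contour
coefficient ``a``.

The predictor is the inverse regression: each parameter is regressed on
``a`` over a training cohort (gate-passing fits only) and a new
subject's parameters are read off the fitted lines, with a homoscedastic
Normal 95% band (±1.96 residual SD) and the BMI estimate mapped through
the standard weight categories. Queries outside the training range of
``a`` are flagged as extrapolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .association import regress_line
from .biometrics import BmiCategory, categorize_bmi
from .synthetic import PARAMETERS

__all__ = [
    "LinePredictor",
    "PredictorModel",
    "Prediction",
    "fit_predictor",
    "predict_from_a",
]

_Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class LinePredictor:
    """One parameter's regression on ``a``: estimate = intercept + slope·a."""

    slope: float
    intercept: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass(frozen=True)
class PredictorModel:
    """Per-parameter linear predictors plus training metadata."""

    lines: dict[str, LinePredictor]
    n_train: int
    a_range_train: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.a_range_train
        if not lo < hi:
            raise ValueError("training range of a must have positive width")
        missing = set(PARAMETERS) - set(self.lines)
        if missing:
            raise ValueError(f"missing predictors for {sorted(missing)}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_train": self.n_train,
            "a_range_train": list(self.a_range_train),
            "lines": {
                name: {
                    "slope": line.slope,
                    "intercept": line.intercept,
                    "residual_sd": line.residual_sd,
                }
                for name, line in self.lines.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictorModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            lines={
                name: LinePredictor(**fields)
                for name, fields in payload["lines"].items()
            },
            n_train=int(payload["n_train"]),
            a_range_train=tuple(payload["a_range_train"]),
        )


@dataclass(frozen=True)
class Prediction:
    """Point estimates with 95% bands for one queried ``a``."""

    a: float
    estimates: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    bmi_category: BmiCategory
    extrapolated: bool


def fit_predictor(cohort: pd.DataFrame, geometry: pd.DataFrame, gate: bool = True) -> PredictorModel:
    """Fit the inverse regressions on a joined cohort/geometry table.

    The residual SD stored per parameter is the regression standard
    error sqrt(SS_res / (n − 2)).
    """
    geo = geometry
    if gate and "passes_gate" in geo.columns:
        geo = geo[geo["passes_gate"].astype(bool)]
    joined = pd.merge(cohort, geo[["subject_id", "a"]], on="subject_id", how="inner")
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 training subjects, got {n}")
    a = joined["a"].to_numpy(dtype=float)
    lines = {}
    for name, column in PARAMETERS.items():
        y = joined[column].to_numpy(dtype=float)
        slope, intercept, residuals = regress_line(a, y)
        residual_sd = math.sqrt(float(np.sum(residuals**2)) / (n - 2))
        lines[name] = LinePredictor(slope=slope, intercept=intercept, residual_sd=residual_sd)
    return PredictorModel(
        lines=lines,
        n_train=n,
        a_range_train=(float(a.min()), float(a.max())),
    )


def predict_from_a(model: PredictorModel, a: float) -> Prediction:
    """Estimate all six body-fat parameters for a new contour coefficient."""
    if not a > 0:
        raise ValueError(f"a must be positive, got {a}")
    estimates, lower, upper = {}, {}, {}
    for name, line in model.lines.items():
        est = line.intercept + line.slope * a
        half = _Z_95 * line.residual_sd
        estimates[name] = est
        lower[name] = est - half
        upper[name] = est + half
    lo, hi = model.a_range_train
    return Prediction(
        a=a,
        estimates=estimates,
        lower=lower,
        upper=upper,
        bmi_category=categorize_bmi(estimates["bmi"]),
        extrapolated=not lo <= a <= hi,
    )
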