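"""Correlation of the contour coefficient ``a`` with body-fat parameters.

For each of the six parameters (weight, BMI, WHR, PBF, BFM, VFA) this
module computes the Pearson correlation with ``a``, the ordinary
least-squares line, a t-test of the zero-slope null (alpha = 0.05), and
a residual-trimming sensitivity analysis (drop the k% of subjects with
the largest absolute vertical residuals from the fitted line, refit,
recompute R²). A correlation is called practically significant when
R² > 0.5, the screening threshold used for this facial-morphometrics
application; no multiple-testing correction is applied across the six
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import PARAMETERS

__all__ = [
    "R2_SIGNIFICANCE",
    "ALPHA",
    "AssociationResult",
    "TrimResult",
    "pearson",
    "regress_line",
    "slope_t_test",
    "trim_and_refit",
    "associate_all",
]

#: R² above which a correlation is reported as practically significant.
R2_SIGNIFICANCE: float = 0.5
#: Significance level for the zero-slope t-test.
ALPHA: float = 0.05


@dataclass(frozen=True)
class TrimResult:
    """Residual-trimming sensitivity result for one parameter."""

    trim_fraction: float
    n_removed: int
    r2_before: float
    r2_after: float


@dataclass(frozen=True)
class AssociationResult:
    """Association of one body-fat parameter with the coefficient ``a``."""

    parameter_name: str
    r: float
    r2: float
    slope: float
    intercept: float
    t_stat: float
    p_value: float
    n: int
    significant: bool
    trims: tuple[TrimResult, ...] = field(default_factory=tuple)


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need 1-D inputs with at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in x or y; correlation undefined")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its square."""
    x, y = _validate_xy(x, y)
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def regress_line(x, y) -> tuple[float, float, np.ndarray]:
    """OLS line of y on x: (slope, intercept, residuals)."""
    x, y = _validate_xy(x, y)
    fit = stats.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    return float(fit.slope), float(fit.intercept), residuals


def slope_t_test(r: float, n: int) -> tuple[float, float]:
    """t-test of the zero-slope null from the correlation coefficient.

    t = r sqrt(n − 2) / sqrt(1 − r²), two-sided p from t(n − 2). A
    perfect correlation (|r| = 1) gives t = ±inf and p = 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return math.copysign(math.inf, r), 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return t, p


def trim_and_refit(x, y, trim_fraction: float) -> TrimResult:
    """Drop the floor(f·n) largest-|residual| points and refit.

    Residuals are vertical deviations from the OLS line of y on x; ties
    are broken by original point order (earlier points removed first), so
    the procedure is deterministic. R² after is the squared Pearson
    correlation of the retained points.
    """
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError(f"trim_fraction must be in [0, 1), got {trim_fraction}")
    x, y = _validate_xy(x, y)
    n = len(x)
    k = int(math.floor(trim_fraction * n))
    if n - k < 3:
        raise ValueError(f"trimming {k} of {n} points leaves fewer than 3")
    _, _, residuals = regress_line(x, y)
    _, r2_before = pearson(x, y)
    if k == 0:
        return TrimResult(trim_fraction, 0, r2_before, r2_before)
    # stable sort on -|residual|: among ties, the earliest original index
    # is removed first
    order = np.argsort(-np.abs(residuals), kind="stable")
    keep = np.setdiff1d(np.arange(n), order[:k])
    _, r2_after = pearson(x[keep], y[keep])
    return TrimResult(trim_fraction, k, r2_before, r2_after)


def associate_all(
    cohort: pd.DataFrame,
    geometry: pd.DataFrame,
    trim_fractions: tuple[float, ...] = (),
    gate: bool = True,
) -> list[AssociationResult]:
    """Associate ``a`` with every body-fat parameter over the joined cohort.

    ``cohort`` needs ``subject_id`` plus the six parameter columns;
    ``geometry`` needs ``subject_id, a`` (and ``passes_gate`` when
    ``gate=True``, in which case failing fits are excluded). Subjects
    missing from either table are dropped by the inner join.
    """
    geo = geometry
    if gate and "passes_gate" in geo.columns:
        geo = geo[geo["passes_gate"].astype(bool)]
    joined = pd.merge(cohort, geo[["subject_id", "a"]], on="subject_id", how="inner")
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} subjects with both cohort data and a "
            "gate-passing fit; need at least 3"
        )
    a = joined["a"].to_numpy(dtype=float)
    results = []
    for name, column in PARAMETERS.items():
        if column not in joined.columns:
            raise ValueError(f"cohort table is missing column {column!r}")
        y = joined[column].to_numpy(dtype=float)
        r, r2 = pearson(a, y)
        slope, intercept, _ = regress_line(a, y)
        t_stat, p_value = slope_t_test(r, len(a))
        trims = tuple(trim_and_refit(a, y, f) for f in trim_fractions)
        results.append(
            AssociationResult(
                parameter_name=name,
                r=r,
                r2=r2,
                slope=slope,
                intercept=intercept,
                t_stat=t_stat,
                p_value=p_value,
                n=len(a),
                significant=r2 > R2_SIGNIFICANCE,
                trims=trims,
            )
        )
    return results
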