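"""Contour normalization and through-origin parabola fitting.

A lower-facial contour is digitised as an ordered point list running from
one earlobe top, around the chin, to the other earlobe top, in arbitrary
device coordinates with a known physical scale. Normalization puts it in
the fixed physical convention: coordinates in mm, the earlobe-to-earlobe
segment horizontal with the chin below it, chin apex at y = 0, and the
symmetry axis (midpoint of the two endpoints) at x = 0.

In that frame the contour is summarised by the single coefficient of the
through-origin parabola y = a x² (least squares), with a fit-quality gate
R² > 0.95. High ``a`` means a narrow, pointy lower face; low ``a`` a wide
one. Because the normalization fixes physical units, ``a`` (mm⁻¹) is
invariant to the device's similarity transform — rotation, translation
and digitisation scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GATE_R2",
    "RawContour",
    "NormalizedContour",
    "ParabolaFit",
    "normalize_contour",
    "fit_parabola",
    "characterize_cohort",
]

#: Per-contour fit-quality gate on R².
GATE_R2: float = 0.95


@dataclass(frozen=True)
class RawContour:
    """Ordered contour points in device coordinates.

    ``scale_mm_per_unit`` converts coordinate units to millimetres;
    ``endpoint_indices`` flag the two earlobe-top anchor points.
    """

    points: np.ndarray  # shape (n, 2)
    scale_mm_per_unit: float
    endpoint_indices: tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(pts) < 3:
            raise ValueError(f"need at least 3 contour points, got {len(pts)}")
        if not np.isfinite(pts).all():
            raise ValueError("contour points must be finite")
        object.__setattr__(self, "points", pts)
        if not self.scale_mm_per_unit > 0:
            raise ValueError("scale_mm_per_unit must be positive")
        i, j = self.endpoint_indices
        if i == j or not (0 <= i < len(pts)) or not (0 <= j < len(pts)):
            raise ValueError(f"invalid endpoint indices {self.endpoint_indices}")


@dataclass(frozen=True)
class NormalizedContour:
    """Contour in the fixed physical frame (mm, chin apex at origin)."""

    points: np.ndarray  # shape (n, 2), mm
    endpoint_indices: tuple[int, int]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class ParabolaFit:
    """Result of the through-origin fit y = a x²."""

    a: float  # mm⁻¹
    r2: float
    n_points: int
    passes_gate: bool


def normalize_contour(
    raw: RawContour,
    quantize_mm: float | None = None,
) -> NormalizedContour:
    """Bring a raw contour into the fixed physical convention.

    Steps: (1) convert to mm via the scale annotation; (2) rotate about
    the centroid so the endpoint segment is horizontal with the contour
    body (the chin) below it; (3) translate so x = 0 at the midpoint of
    the endpoint x-coordinates and y = 0 at the chin apex — the vertex of
    an auxiliary least-squares parabola y = a x² + c, which is the
    contour's lowermost point even when no sampled point falls exactly on
    the vertex. Point order is preserved.

    ``quantize_mm`` optionally snaps the normalized coordinates to a grid
    of that pitch, emulating manual digitisation on grid paper.

    Raises
    ------
    ValueError
        If the two endpoints coincide (rotation undefined).
    """
    pts = raw.points * raw.scale_mm_per_unit
    i, j = raw.endpoint_indices
    e1, e2 = pts[i], pts[j]
    chord = e2 - e1
    span = float(np.hypot(*chord))
    extent = float(np.abs(pts - pts.mean(axis=0)).max()) or 1.0
    if span <= 1e-9 * extent:
        raise ValueError("endpoint points coincide; rotation undefined")

    angle = np.arctan2(chord[1], chord[0])
    centroid = pts.mean(axis=0)
    c, s = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, -s], [s, c]])
    pts = (pts - centroid) @ rot.T + centroid

    # chin-down: the contour body must lie below the (now horizontal)
    # endpoint line; otherwise flip by 180 degrees about the centroid.
    body = np.delete(pts[:, 1], [i, j]) if len(pts) > 2 else pts[:, 1]
    endpoint_y = 0.5 * (pts[i, 1] + pts[j, 1])
    if np.mean(body) > endpoint_y:
        pts = 2 * centroid - pts

    pts[:, 0] -= 0.5 * (pts[i, 0] + pts[j, 0])
    # vertical anchor: vertex offset c of y = a x² + c (falls back to the
    # lowest sampled point when the design is degenerate, e.g. all x equal)
    design = np.column_stack([pts[:, 0] ** 2, np.ones(len(pts))])
    if np.linalg.matrix_rank(design) == 2:
        (_, c), *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
        pts[:, 1] -= c
    else:
        pts[:, 1] -= pts[:, 1].min()
    if quantize_mm is not None:
        if not quantize_mm > 0:
            raise ValueError("quantize_mm must be positive")
        pts = np.round(pts / quantize_mm) * quantize_mm
    return NormalizedContour(points=pts, endpoint_indices=raw.endpoint_indices)


def fit_parabola(contour: NormalizedContour) -> ParabolaFit:
    """Least-squares through-origin parabola y = a x².

    The closed form is a = Σ x² y / Σ x⁴. R² is 1 − SS_res/SS_tot with
    SS_tot about the mean of y (the convention under which the 0.95 gate
    is meaningful for a constrained model); a zero-variance y (flat
    contour) is reported as R² = 1.

    Raises
    ------
    ValueError
        Fewer than 3 points, or all x = 0 (zero denominator).
    """
    x, y = contour.x, contour.y
    if len(x) < 3:
        raise ValueError(f"need at least 3 points to fit, got {len(x)}")
    x2 = x * x
    denom = float(np.sum(x2 * x2))
    if denom <= 0.0:
        raise ValueError("all x coordinates are zero; fit undefined")
    a = float(np.sum(x2 * y) / denom)
    ss_res = float(np.sum((y - a * x2) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return ParabolaFit(a=a, r2=r2, n_points=len(x), passes_gate=r2 > GATE_R2)


def characterize_cohort(
    contours: Mapping[str, RawContour],
    gate: bool = True,
    quantize_mm: float | None = None,
) -> pd.DataFrame:
    """Normalize and fit every contour; one row per subject.

    Returns a table with columns ``subject_id, a, r2, n_points,
    passes_gate``. Degenerate contours are logged and skipped (the run
    continues). With ``gate=True``, downstream association input should
    keep only ``passes_gate`` rows; the flag is always reported.
    """
    rows = []
    for subject_id, raw in contours.items():
        try:
            fit = fit_parabola(normalize_contour(raw, quantize_mm=quantize_mm))
        except (ValueError, TypeError) as exc:
            logger.warning("contour %s excluded: %s", subject_id, exc)
            continue
        rows.append(
            {
                "subject_id": subject_id,
                "a": fit.a,
                "r2": fit.r2,
                "n_points": fit.n_points,
                "passes_gate": fit.passes_gate,
            }
        )
    table = pd.DataFrame(
        rows, columns=["subject_id", "a", "r2", "n_points", "passes_gate"]
    )
    if gate and len(table) and not table["passes_gate"].all():
        n_fail = int((~table["passes_gate"]).sum())
        logger.warning("%d contour fits fail the R² > %.2f gate", n_fail, GATE_R2)
    return table
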