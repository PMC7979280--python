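"""CSV readers and writers for cohort tables and contour point lists.

Cohort CSV dialect: header ``subject_id,weight_kg,height_cm,bmi,whr,
pbf_pct,bfm_kg,vfa_cm2[,true_a]``; unknown columns are preserved through
round trips. Contour CSV dialect: two comment lines carrying the
physical scale and the endpoint indices, then ``x,y`` rows in contour
order::

    # scale_mm_per_unit=0.0125
    # endpoints=0,46
    x,y
    -12.5,3.25
    ...

Numbers are written with shortest round-trip precision (Python repr), so
write-then-read is exact and write-read-write is byte-stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .geometry import RawContour
from .synthetic import SubjectRecord

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "cohort_frame",
    "read_contour",
    "write_contour",
    "read_contour_dir",
    "write_contour_dir",
]

COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "weight_kg",
    "height_cm",
    "bmi",
    "whr",
    "pbf_pct",
    "bfm_kg",
    "vfa_cm2",
)
_NUMERIC = COHORT_COLUMNS[1:]


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame (true_a column only when any record has one)."""
    rows = []
    for rec in records:
        row = {col: getattr(rec, col) for col in COHORT_COLUMNS}
        if rec.true_a is not None:
            row["true_a"] = rec.true_a
        row.update(rec.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(path: str | Path, records: Sequence[SubjectRecord]) -> None:
    frame = cohort_frame(records)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(frame.columns) + "\n")
        for _, row in frame.iterrows():
            fh.write(
                ",".join(
                    str(v) if isinstance(v, str) else repr(float(v))
                    for v in row.to_numpy()
                )
                + "\n"
            )


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Parse a cohort CSV, validating columns and numeric cells.

    Raises ValueError naming any missing required column, or naming the
    column and line number of a non-numeric cell.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing column(s) {missing}")
    numeric = list(_NUMERIC) + (["true_a"] if "true_a" in frame.columns else [])
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"non-numeric value in column {col!r}, line {line}")
        frame[col] = coerced
    extra_cols = [c for c in frame.columns if c not in numeric and c != "subject_id"]
    records = []
    for _, row in frame.iterrows():
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                **{c: float(row[c]) for c in _NUMERIC},
                true_a=float(row["true_a"]) if "true_a" in frame.columns else None,
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_contour(path: str | Path, contour: RawContour) -> None:
    i, j = contour.endpoint_indices
    lines = [
        f"# scale_mm_per_unit={contour.scale_mm_per_unit!r}",
        f"# endpoints={i},{j}",
        "x,y",
    ]
    lines += [f"{float(x)!r},{float(y)!r}" for x, y in contour.points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_contour(path: str | Path, flip_y: bool = False) -> RawContour:
    """Parse a contour CSV; ``flip_y`` negates y for image-style (y-down)
    digitisations."""
    scale = None
    endpoints = None
    points: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("scale_mm_per_unit="):
                    scale = float(body.split("=", 1)[1])
                elif body.startswith("endpoints="):
                    i, j = body.split("=", 1)[1].split(",")
                    endpoints = (int(i), int(j))
                continue
            if line == "x,y":
                continue
            try:
                x_s, y_s = line.split(",")
                points.append((float(x_s), float(y_s)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad point row {line!r}") from exc
    if scale is None:
        raise ValueError(f"{path}: missing '# scale_mm_per_unit=' annotation")
    if endpoints is None:
        endpoints = (0, len(points) - 1)
    if flip_y:
        points = [(x, -y) for x, y in points]
    return RawContour(
        points=points, scale_mm_per_unit=scale, endpoint_indices=endpoints
    )


def write_contour_dir(directory: str | Path, contours: dict[str, RawContour]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for subject_id, contour in contours.items():
        write_contour(directory / f"{subject_id}.csv", contour)


def read_contour_dir(
    directory: str | Path, flip_y: bool = False
) -> dict[str, RawContour]:
    """Read every ``*.csv`` contour in a directory, keyed by file stem.

    Unreadable files are skipped with a warning (row-level error policy);
    an empty directory yields an empty mapping.
    """
    import logging

    logger = logging.getLogger(__name__)
    contours: dict[str, RawContour] = {}
    for path in sorted(Path(directory).glob("*.csv")):
        try:
            contours[path.stem] = read_contour(path, flip_y=flip_y)
        except (ValueError, OSError) as exc:
            logger.warning("contour file %s excluded: %s", path, exc)
    return contours
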