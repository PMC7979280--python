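"""Anthropometric primitives: BMI, BMI weight categories, waist-to-hip ratio.

These are the externally measurable body-fat quantities. BMI boundaries
(18.5 / 25 / 30 kg/m²) follow the WHO convention with boundary values
assigned to the higher category, so every positive BMI has exactly one
category.
"""

from __future__ import annotations

from enum import Enum

__all__ = ["BmiCategory", "compute_bmi", "categorize_bmi", "compute_whr"]


class BmiCategory(str, Enum):
    """Standard BMI-based weight category."""

    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m², from weight in kg and height in cm.

    Raises
    ------
    ValueError
        If weight or height is not strictly positive.
    """
    if not weight_kg > 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if not height_cm > 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    return weight_kg / (height_cm / 100.0) ** 2


def categorize_bmi(bmi: float) -> BmiCategory:
    """Map a positive BMI to its weight category.

    Cutoffs: < 18.5 underweight, [18.5, 25) normal, [25, 30) overweight,
    >= 30 obese.
    """
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return BmiCategory.UNDERWEIGHT
    if bmi < 25.0:
        return BmiCategory.NORMAL
    if bmi < 30.0:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


def compute_whr(waist_cm: float, hip_cm: float) -> float:
    """Waist-to-hip ratio from the two circumferences (cm)."""
    if not waist_cm > 0:
        raise ValueError(f"waist circumference must be positive, got {waist_cm}")
    if not hip_cm > 0:
        raise ValueError(f"hip circumference must be positive, got {hip_cm}")
    return waist_cm / hip_cm
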