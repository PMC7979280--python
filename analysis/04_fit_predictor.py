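"""Invert the association: fit the parameter-on-a regressions and predict
body-fat parameters (with 95% bands and BMI category) for example faces.

Reads results/cohort.csv + results/geometry.csv; writes
results/predictor.json.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from facefat import fit_predictor, predict_from_a
from facefat import io as fio

EXAMPLE_A = (0.07, 0.095, 0.12)  # wide, average and pointy lower faces


def main() -> None:
    cohort = fio.cohort_frame(fio.read_cohort(ROOT / "results" / "cohort.csv"))
    geometry = pd.read_csv(ROOT / "results" / "geometry.csv")
    model = fit_predictor(cohort, geometry)
    model.to_json(ROOT / "results" / "predictor.json")

    lo, hi = model.a_range_train
    print(f"trained on {model.n_train} subjects, a in [{lo:.4f}, {hi:.4f}]")
    for a in EXAMPLE_A:
        pred = predict_from_a(model, a)
        bmi, pbf = pred.estimates["bmi"], pred.estimates["pbf"]
        print(
            f"  a = {a:.3f}: BMI {bmi:5.1f} "
            f"[{pred.lower['bmi']:.1f}, {pred.upper['bmi']:.1f}] "
            f"({pred.bmi_category.value}), PBF {pbf:5.1f} % "
            f"[{pred.lower['pbf']:.1f}, {pred.upper['pbf']:.1f}]"
        )
    print("wrote results/predictor.json")


if __name__ == "__main__":
    main()
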