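"""Normalize every simulated contour and fit the through-origin parabola
y = a x², gating on fit R² > 0.95.

Reads scratch/sim/contours/ (run 01 first); writes results/geometry.csv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from facefat import characterize_cohort
from facefat import io as fio


def main() -> None:
    contours = fio.read_contour_dir(ROOT / "scratch" / "sim" / "contours")
    if not contours:
        raise SystemExit("no contours found; run analysis/01_simulate_cohort.py first")
    geometry = characterize_cohort(contours, gate=True)
    geometry.to_csv(ROOT / "results" / "geometry.csv", index=False)

    print(f"fitted {len(geometry)} contours")
    print(f"  a range      {geometry['a'].min():.4f} .. {geometry['a'].max():.4f}")
    print(f"  fit R2 range {geometry['r2'].min():.4f} .. {geometry['r2'].max():.4f}")
    print(f"  gate (R2 > 0.95) passed by {int(geometry['passes_gate'].sum())}/{len(geometry)}")
    print("wrote results/geometry.csv")


if __name__ == "__main__":
    main()
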