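"""Prediction curves with 95 % confidence bands along each axis.

Each focal variable sweeps its observed range while the other two are held at
their dataset means; bands come from the delta method on ln(MO2). Grids are
written as CSV for downstream plotting or tabulation.
"""

from pathlib import Path

import numpy as np

from salmo_mo2 import dataset, estimate, evaluate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = dataset.read_dataset(OUT / "dataset_refined.csv")
    fit = estimate.fit_stage2_nlme(ds, estimate.fit_stage1_loglinear(ds))
    df = ds.to_dataframe()
    means = {
        "W": float(df.body_weight_kg.mean()),
        "T": float(df.temperature_c.mean()),
        "U": float(df.rel_speed_bl_s.mean()),
    }
    spans = {
        "W": (df.body_weight_kg.min(), df.body_weight_kg.max()),
        "T": (df.temperature_c.min(), df.temperature_c.max()),
        "U": (df.rel_speed_bl_s.min(), df.rel_speed_bl_s.max()),
    }
    for axis in ("W", "T", "U"):
        lo, hi = spans[axis]
        held = {k: v for k, v in means.items() if k != axis}
        grid = evaluate.prediction_grid(fit, axis, (lo, hi, 50), held)
        grid.to_frame().to_csv(OUT / f"grid_{axis}.csv", index=False)
        mid = len(grid.values) // 2
        print(f"{axis} sweep {lo:g}-{hi:g} (others at {held}): "
              f"midpoint MO2 = {grid.predicted[mid]:.1f} "
              f"[{grid.lower[mid]:.1f}, {grid.upper[mid]:.1f}] mg O2/kg/h")


if __name__ == "__main__":
    main()
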