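"""Apply the inclusion criteria and model-assumption filters.

Reads results/dataset_raw.csv, removes entries measured outside the target
conditions and entries where the exponential model is known to plateau
(>= 23 °C; 100 % U_crit), and writes the refined table plus filter reports.
"""

from pathlib import Path

from salmo_mo2 import dataset

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = dataset.read_dataset(OUT / "dataset_raw.csv")
    ds_inc, rep_inc = dataset.apply_inclusion_criteria(ds)
    ds_ref, rep_mod = dataset.apply_model_assumption_filters(ds_inc)
    dataset.write_dataset(ds_ref, OUT / "dataset_refined.csv")
    rep_inc.to_json(OUT / "filter_inclusion.json")
    rep_mod.to_json(OUT / "filter_assumptions.json")
    s = dataset.summarize(ds_ref)
    print(f"{len(ds)} raw -> {len(ds_ref)} refined entries")
    for var, (lo, hi) in s.ranges.items():
        print(f"  {var}: {lo:g}-{hi:g}")


if __name__ == "__main__":
    main()
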