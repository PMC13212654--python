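"""Generate the synthetic respirometry compilation used by the later steps.

Emits the raw 96-entry table (including the 23 °C treatment group and the
100 % U_crit rows) plus the generating-truth sidecar, under results/.
"""

import sys
from pathlib import Path

from salmo_mo2 import dataset, synth

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = synth.default_config(seed=seed)
    ds, truth = synth.generate_dataset(cfg)
    dataset.write_dataset(ds, OUT / "dataset_raw.csv")
    synth.write_truth_json(truth, OUT / "truth.json")
    synth.config_to_yaml(cfg, OUT / "synthetic_config.yaml")
    print(f"wrote {len(ds)} raw entries (seed={seed}) to {OUT/'dataset_raw.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
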