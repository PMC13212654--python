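"""Diagnostics, legacy-model comparison and physiological contrasts.

Scores the refit and the legacy coefficient set against the refined dataset,
derives Q10 and the coefficient contrasts, and writes the comparison table.
"""

import json
from pathlib import Path

from salmo_mo2 import dataset, estimate, evaluate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = dataset.read_dataset(OUT / "dataset_refined.csv")
    fit_payload = json.loads((OUT / "fit.json").read_text())
    coefs = estimate.CoefficientSet(**fit_payload["coefficients"])

    start = estimate.fit_stage1_loglinear(ds)
    fit = estimate.fit_stage2_nlme(ds, start)
    diag = evaluate.diagnostics(fit, ds)
    diag.to_json(OUT / "diagnostics.json", include_residuals=True)
    cand, legacy = evaluate.compare_models(ds, coefs)
    table = evaluate.coefficient_table([
        ("refit (nonlinear mixed-effects)", fit, cand),
        ("legacy (Grøttum & Sigholt 1998)", estimate.LEGACY_MODEL, legacy),
    ])
    (OUT / "report.txt").write_text(table + "\n")
    print(table)

    contrast = evaluate.coefficient_contrast(estimate.LEGACY_MODEL, coefs)
    (OUT / "contrasts.json").write_text(json.dumps(contrast.to_dict(), indent=2))
    print(f"\nintercept shift: {contrast.intercept_pct_change:+.1f} %")
    print(f"Q10: {contrast.q10_old:.2f} -> {contrast.q10_new:.2f} "
          f"({contrast.q10_sensitivity_pct:+.0f} % temperature sensitivity)")
    print(f"speed multiplier: {contrast.d_pct_change:+.1f} %")


if __name__ == "__main__":
    main()
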