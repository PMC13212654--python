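"""Two-stage coefficient estimation on the refined dataset.

Stage 1: log-linear OLS for starting values. Stage 2: maximum-likelihood
nonlinear mixed-effects fit with a per-study random intercept, followed by
the two-way interaction screen. Writes fit.json and interactions.json.
"""

from pathlib import Path

from salmo_mo2 import dataset, estimate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = dataset.read_dataset(OUT / "dataset_refined.csv")
    start = estimate.fit_stage1_loglinear(ds)
    fit = estimate.fit_stage2_nlme(ds, start)
    fit.to_json(OUT / "fit.json")
    screen = estimate.screen_interactions(ds, fit)
    screen.to_json(OUT / "interactions.json")
    c, se = fit.coefficients, fit.se
    print(f"start values: a={start.a:.2f} b={start.b:.3f} c={start.c:.4f} d={start.d:.3f}")
    print(f"fit ({'converged' if fit.converged else 'NOT converged'}, "
          f"{fit.n_studies} studies, {fit.n_entries} entries):")
    for k in "abcd":
        print(f"  {k} = {getattr(c, k):.4f} ± {se[k]:.4f}")
    print(f"  sigma_study = {fit.sigma_study:.2f}, sigma_resid = {fit.sigma_resid:.2f}")
    ci = estimate.wald_confint(fit)
    print("95% CI:", {k: (round(v[0], 3), round(v[1], 3)) for k, v in ci.items()})
    print("retained interactions:", screen.retained or "none")


if __name__ == "__main__":
    main()
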