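"""Two-stage estimation: stage-1 OLS, marginal likelihood, NLME fit, CIs."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from salmo_mo2 import (
    CoefficientSet,
    apply_inclusion_criteria,
    apply_model_assumption_filters,
    default_config,
    fit_stage1_loglinear,
    fit_stage2_nlme,
    generate_dataset,
    marginal_loglik,
    screen_interactions,
    wald_confint,
)
from salmo_mo2.dataset import Dataset, RespirometryEntry
from salmo_mo2.estimate import EstimationError, _Problem

from conftest import make_entry


class TestStage1:
    def test_exact_recovery_on_noise_free_data(self, noise_free_dataset):
        ds, truth = noise_free_dataset
        est = fit_stage1_loglinear(ds)
        for k in "abcd":
            assert getattr(est, k) == pytest.approx(getattr(truth, k), rel=1e-10)

    def test_matches_normal_equations_oracle(self):
        # hand-built entries with an invertible design; independent 4x4 solve
        specs = [(0.3, 5.0, 0.5, 210.0), (0.6, 8.0, 1.0, 260.0), (1.2, 12.0, 1.7, 340.0),
                 (2.4, 16.0, 2.3, 460.0), (0.9, 10.0, 1.3, 300.0)]
        entries = [
            RespirometryEntry("s", f"g{i}", w, 35.0, t, u, y)
            for i, (w, t, u, y) in enumerate(specs)
        ]
        est = fit_stage1_loglinear(Dataset(entries))
        X = np.array([[1.0, math.log(w), t, u] for w, t, u, _ in specs])
        z = np.array([math.log(y) for *_, y in specs])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        assert est.a == pytest.approx(math.exp(beta[0]), rel=1e-8)
        assert est.b == pytest.approx(beta[1], rel=1e-8)
        assert est.c == pytest.approx(math.exp(beta[2]), rel=1e-8)
        assert est.d == pytest.approx(math.exp(beta[3]), rel=1e-8)

    def test_constant_speed_is_collinear(self):
        entries = [make_entry(body_weight=w, temperature=t)
                   for w, t in [(0.3, 5), (0.5, 8), (0.8, 11), (1.2, 14), (2.0, 17)]]
        with pytest.raises(EstimationError, match="collinear: rel_speed"):
            fit_stage1_loglinear(Dataset(entries))

    def test_too_few_entries(self):
        with pytest.raises(EstimationError, match="5 entries"):
            fit_stage1_loglinear(Dataset([make_entry()]))


class TestMarginalLoglik:
    COEFS = CoefficientSet(80.0, -0.15, 1.04, 1.6)

    def test_zero_sigma_study_equals_iid_gaussian(self, toy_two_study):
        se = 40.0
        ll = marginal_loglik(self.COEFS, 0.0, se, toy_two_study)
        resid = np.array([
            e.mo2 - self.COEFS.a * e.body_weight**self.COEFS.b
            * self.COEFS.c**e.temperature * self.COEFS.d**e.rel_speed
            for e in toy_two_study
        ])
        expected = float(np.sum(stats.norm.logpdf(resid, scale=se)))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_quadrature_oracle(self, toy_two_study):
        su, se = 12.0, 40.0
        ll = marginal_loglik(self.COEFS, su, se, toy_two_study)
        # trapezoid integration of the random effect on a 2001-point grid
        total = 0.0
        grid = np.linspace(-10 * su, 10 * su, 2001)
        for sid in ("s1", "s2"):
            sub = [e for e in toy_two_study if e.study_id == sid]
            x = np.array([
                e.body_weight**self.COEFS.b * self.COEFS.c**e.temperature
                * self.COEFS.d**e.rel_speed for e in sub
            ])
            y = np.array([e.mo2 for e in sub])
            dens = [
                float(np.prod(stats.norm.pdf(y, (self.COEFS.a + u) * x, se))
                      * stats.norm.pdf(u, 0.0, su))
                for u in grid
            ]
            total += math.log(np.trapezoid(dens, grid))
        assert ll == pytest.approx(total, abs=1e-6)

    def test_permutation_invariant_within_study(self, toy_two_study):
        ll = marginal_loglik(self.COEFS, 12.0, 40.0, toy_two_study)
        entries = list(toy_two_study)
        perm = Dataset([entries[2], entries[0], entries[1]] + entries[3:], "perm")
        assert marginal_loglik(self.COEFS, 12.0, 40.0, perm) == pytest.approx(ll, abs=1e-12)

    def test_nonpositive_sigma_resid_rejected(self, toy_two_study):
        with pytest.raises(ValueError):
            marginal_loglik(self.COEFS, 1.0, 0.0, toy_two_study)

    def test_analytic_gradient_matches_finite_differences(self, refined_dataset):
        ds, _ = refined_dataset
        prob = _Problem(ds, "T_U")
        theta = np.array([75.0, -0.2, math.log(1.05), math.log(1.6), 0.003,
                          math.log(6.0), math.log(50.0)])

        def f(t):
            ll, _ = prob.loglik_and_grad(t[0], t[1], t[2], t[3], t[4],
                                         math.exp(t[5]), math.exp(t[6]))
            return ll

        _, g = prob.loglik_and_grad(theta[0], theta[1], theta[2], theta[3],
                                    theta[4], math.exp(theta[5]), math.exp(theta[6]))
        for k in range(7):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            num = (f(tp) - f(tm)) / (2 * h)
            assert g[k] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestStage2:
    def test_noise_free_single_study_recovers_truth(self, single_study_config):
        cfg = single_study_config
        cfg.truth.sigma_study = 0.0
        cfg.truth.sigma_resid = 0.0
        ds, truth = generate_dataset(cfg)
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        for k in "abcd":
            assert getattr(fit.coefficients, k) == pytest.approx(getattr(truth, k), rel=1e-6)
        assert fit.sigma_study == 0.0
        assert fit.sigma_resid < 1e-3  # residual SD driven towards its floor
        assert any("one study" in w for w in fit.warnings)

    def test_equals_nls_oracle_when_sigma_study_zero(self):
        cfg = default_config(seed=7)
        cfg.truth.sigma_study = 0.0
        ds, _ = generate_dataset(cfg)
        ds, _ = apply_inclusion_criteria(ds)
        ds, _ = apply_model_assumption_filters(ds)
        start = fit_stage1_loglinear(ds)
        fit = fit_stage2_nlme(ds, start, fix_sigma_study=0.0)
        W = np.array([e.body_weight for e in ds])
        T = np.array([e.temperature for e in ds])
        U = np.array([e.rel_speed for e in ds])
        y = np.array([e.mo2 for e in ds])

        def resid(p):
            return y - p[0] * W ** p[1] * p[2] ** T * p[3] ** U

        nls = optimize.least_squares(resid, np.array(start.as_tuple()), method="lm",
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        for est, ref in zip(fit.coefficients.as_tuple(), nls.x):
            assert est == pytest.approx(ref, rel=1e-4)

    def test_fit_converges_on_default_data(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        assert fit.converged
        assert fit.gradient_norm < 1e-6
        assert fit.n_entries == 76 and fit.n_studies == 7
        assert fit.sigma_resid > 0 and fit.sigma_study >= 0
        # vcov symmetric PSD
        v = fit.vcov
        assert np.allclose(v, v.T)
        assert np.all(np.linalg.eigvalsh(v) > -1e-10)

    def test_loglik_is_local_maximum(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        base = marginal_loglik(fit.coefficients, fit.sigma_study, fit.sigma_resid, ds)
        rng = np.random.default_rng(0)
        c = fit.coefficients
        for _ in range(100):
            k = rng.integers(0, 4)
            eps = rng.choice([-1, 1]) * rng.uniform(1e-4, 1e-2)
            vals = dict(a=c.a, b=c.b, c=c.c, d=c.d)
            vals["abcd"[k]] *= 1 + eps
            pert = CoefficientSet(**vals)
            assert marginal_loglik(pert, fit.sigma_study, fit.sigma_resid, ds) <= base + 1e-9

    def test_invariant_to_entry_order_and_study_labels(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        rng = np.random.default_rng(1)
        idx = rng.permutation(len(ds))
        relabel = {sid: f"study_{i:02d}" for i, sid in enumerate(reversed(ds.study_ids))}
        shuffled = Dataset(
            [
                RespirometryEntry(
                    relabel[ds[i].study_id], ds[i].treatment_id, ds[i].body_weight,
                    ds[i].fork_length, ds[i].temperature, ds[i].rel_speed, ds[i].mo2,
                    ds[i].pct_ucrit, ds[i].group_size, ds[i].n_replicates,
                )
                for i in idx
            ],
            "shuffled",
        )
        fit2 = fit_stage2_nlme(shuffled, fit_stage1_loglinear(shuffled))
        for k in "abcd":
            assert getattr(fit2.coefficients, k) == pytest.approx(
                getattr(fit.coefficients, k), rel=1e-7
            )
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_nonfinite_start_rejected(self, refined_dataset):
        ds, _ = refined_dataset
        with pytest.raises(EstimationError):
            fit_stage2_nlme(ds, CoefficientSet(80.0, math.nan, 1.04, 1.6))


class TestInteractionScreen:
    def test_no_interaction_on_null_data(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        report = screen_interactions(ds, fit)
        assert set(report.candidates) == {"lnW_T", "lnW_U", "T_U"}
        for cand in report.candidates.values():
            if cand["evaluable"]:
                assert 0.0 <= cand["lrt_p"] <= 1.0
        assert set(report.retained) <= set(report.candidates)

    def test_strong_planted_term_detected(self):
        cfg = default_config(seed=42)
        cfg.truth.gamma_tu = 0.06
        ds, _ = generate_dataset(cfg)
        ds, _ = apply_inclusion_criteria(ds)
        ds, _ = apply_model_assumption_filters(ds)
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        report = screen_interactions(ds, fit)
        assert report.retained == ["T_U"]
        cand = report.candidates["T_U"]
        assert cand["gamma"] == pytest.approx(0.06, abs=0.02)


class TestWaldIntervals:
    def test_intervals_contain_estimate(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        ci = wald_confint(fit)
        for k in "abcd":
            lo, hi = ci[k]
            assert lo <= getattr(fit.coefficients, k) <= hi

    def test_width_scales_with_z_ratio(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        ci95 = wald_confint(fit, 0.95)
        ci99 = wald_confint(fit, 0.99)
        ratio = stats.norm.ppf(0.995) / stats.norm.ppf(0.975)
        # widths on the optimisation scale: a, b natural; c, d logarithmic
        for k, f in [("a", lambda lo, hi: hi - lo), ("b", lambda lo, hi: hi - lo),
                     ("c", lambda lo, hi: math.log(hi / lo)), ("d", lambda lo, hi: math.log(hi / lo))]:
            w95 = f(*ci95[k])
            w99 = f(*ci99[k])
            assert w99 / w95 == pytest.approx(ratio, rel=1e-9)

    def test_zero_se_collapses_interval(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        fit.se_opt = np.zeros_like(fit.se_opt)
        ci = wald_confint(fit)
        for k in "abcd":
            lo, hi = ci[k]
            assert lo == pytest.approx(hi)
            assert lo == pytest.approx(getattr(fit.coefficients, k))

    def test_level_domain_checked(self, refined_dataset):
        ds, _ = refined_dataset
        fit = fit_stage2_nlme(ds, fit_stage1_loglinear(ds))
        with pytest.raises(ValueError):
            wald_confint(fit, 1.0)
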