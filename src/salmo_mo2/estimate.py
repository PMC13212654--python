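"""Two-stage coefficient estimation for the multiplicative MO2 model.

Stage 1 linearises MO2 = a * W^b * c^T * d^U by taking logs and fits an
ordinary least-squares regression of ln(MO2) on {1, ln W, T, U}; the
coefficients are back-transformed into starting values (a = exp(intercept),
b = slope of ln W, c = exp(slope of T), d = exp(slope of U)).

Stage 2 maximises the exact Gaussian marginal likelihood of a nonlinear
mixed-effects model on the untransformed scale. Within study i, with basis
values x_ij = W^b c^T d^U and an additive random intercept u_i ~ N(0, s_u^2),

    y_i ~ Normal(a * x_i,  s_u^2 * x_i x_i' + s_e^2 * I).

The rank-one covariance is handled in closed form (matrix determinant lemma
and Sherman–Morrison), and the marginal log-likelihood carries an analytic
gradient, so the quasi-Newton optimiser converges to tight tolerances.
Variance components are optimised as log-SDs for positivity, and c, d as
ln c, ln d. Standard errors come from the observed information (numerical
Hessian of the negative log-likelihood at the optimum, built from central
differences of the analytic gradient) and are delta-method-transformed back
to the natural coefficient scale.

Interaction screening augments the log-scale mean with one product term
(lnW*T, lnW*U or T*U), refits, and compares by likelihood-ratio test and AIC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .dataset import Dataset

__all__ = [
    "CoefficientSet",
    "FitResult",
    "InteractionReport",
    "EstimationError",
    "REVISED_MODEL",
    "LEGACY_MODEL",
    "fit_stage1_loglinear",
    "marginal_loglik",
    "fit_stage2_nlme",
    "screen_interactions",
    "wald_confint",
]

#: Gradient infinity-norm below which a fit is declared converged.
GRADIENT_TOL = 1e-6
#: Relative step for the numerical Hessian (central differences of the gradient).
HESSIAN_STEP = 1e-5

INTERACTION_TERMS = ("lnW_T", "lnW_U", "T_U")


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated from the data provided."""


@dataclass(frozen=True)
class CoefficientSet:
    """The four coefficients of MO2 = a * W^b * c^T * d^U."""

    a: float  # mg O2 kg^-1 h^-1 at W = 1 kg, T = 0 °C, U = 0 BL/s
    b: float  # mass-specific allometric exponent (dimensionless)
    c: float  # per-°C multiplier
    d: float  # per-(BL/s) multiplier

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0 and self.d > 0):
            raise ValueError("a, c and d must be positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


#: Refined coefficient set estimated from the seven-study group-respirometry
#: compilation (AquaGen-strain post-smolts, 0.2–3.38 kg, 3–18 °C).
REVISED_MODEL = CoefficientSet(a=79.7, b=-0.14, c=1.04, d=1.63)

#: Grøttum & Sigholt (1998) coefficients, the legacy industry-standard model.
LEGACY_MODEL = CoefficientSet(a=61.6, b=-0.33, c=1.03, d=1.79)


# ---------------------------------------------------------------------------
# internal problem representation

_PRED_NAMES = {"lnW": "body_weight", "T": "temperature", "U": "rel_speed"}


class _Problem:
    """Data grouped by study, with optional interaction product term."""

    def __init__(self, ds: Dataset, interaction: str | None = None):
        if interaction is not None and interaction not in INTERACTION_TERMS:
            raise ValueError(f"unknown interaction term: {interaction}")
        self.interaction = interaction
        self.study_ids = sorted({e.study_id for e in ds})
        self.groups = []
        for sid in self.study_ids:
            sub = [e for e in ds if e.study_id == sid]
            lnW = np.array([math.log(e.body_weight) for e in sub])
            T = np.array([e.temperature for e in sub], dtype=float)
            U = np.array([e.rel_speed for e in sub], dtype=float)
            y = np.array([e.mo2 for e in sub], dtype=float)
            if interaction == "lnW_T":
                P = lnW * T
            elif interaction == "lnW_U":
                P = lnW * U
            elif interaction == "T_U":
                P = T * U
            else:
                P = np.zeros_like(T)
            self.groups.append((lnW, T, U, P, y))
        self.n_entries = sum(len(g[4]) for g in self.groups)
        self.n_studies = len(self.groups)
        self.n_fixed = 4 + (1 if interaction else 0)
        self.y_scale = float(np.mean([np.mean(np.abs(g[4])) for g in self.groups]))

    def loglik_and_grad(self, a, b, lnc, lnd, gamma, sigma_study, sigma_resid):
        """Exact marginal log-likelihood and its gradient.

        Gradient order: (a, b, lnc, lnd[, gamma], ln sigma_study, ln sigma_resid);
        gamma and sigma_study slots are always computed, callers slice.
        """
        with np.errstate(over="ignore", invalid="ignore"):
            return self._loglik_and_grad(a, b, lnc, lnd, gamma, sigma_study, sigma_resid)

    def _loglik_and_grad(self, a, b, lnc, lnd, gamma, sigma_study, sigma_resid):
        v = sigma_study**2
        s2 = sigma_resid**2
        ll = 0.0
        grad = np.zeros(7)  # a, b, lnc, lnd, gamma, d/d ln su, d/d ln se
        for lnW, T, U, P, y in self.groups:
            n = len(y)
            # clip the exponent: keeps the objective finite while the
            # optimiser explores extreme trial points
            x = np.exp(np.clip(b * lnW + T * lnc + U * lnd + gamma * P, -500.0, 500.0))
            r = y - a * x
            x2 = x * x
            nx2 = float(np.sum(x2))
            S = s2 + v * nx2
            q = float(x @ r)
            rr = float(r @ r)
            logdet = (n - 1) * math.log(s2) + math.log(S)
            Q = (rr - v * q * q / S) / s2
            ll += -0.5 * (n * math.log(2 * math.pi) + logdet + Q)

            # fixed effects
            grad[0] += q / S
            ts = (lnW, T, U, P)
            for k in range(4):
                t_k = ts[k]
                A = float(x2 @ t_k)
                B = float((x * r) @ t_k)
                dlogdet = 2.0 * v * A / S
                dQ = (-2.0 * a * B - 2.0 * v * q * (B - a * A) / S + 2.0 * v * v * q * q * A / (S * S)) / s2
                grad[1 + k] += -0.5 * (dlogdet + dQ)
            # variance components (chain rule to log-SD scale)
            dll_dv = -0.5 * (nx2 / S - q * q / (S * S))
            grad[5] += 2.0 * v * dll_dv
            dll_ds2 = -0.5 * ((n - 1) / s2 + 1.0 / S - Q / s2 + v * q * q / (s2 * S * S))
            grad[6] += 2.0 * s2 * dll_ds2
        return ll, grad


def _mean_mo2(coefs: CoefficientSet, lnW, T, U, P=0.0, gamma=0.0):
    return coefs.a * np.exp(coefs.b * np.asarray(lnW) + np.asarray(T) * math.log(coefs.c)
                            + np.asarray(U) * math.log(coefs.d) + gamma * np.asarray(P))


# ---------------------------------------------------------------------------
# stage 1

def fit_stage1_loglinear(ds: Dataset) -> CoefficientSet:
    """OLS of ln(MO2) on {1, ln W, T, U}, back-transformed to (a, b, c, d)."""
    if len(ds) < 5:
        raise EstimationError(f"need at least 5 entries, got {len(ds)}")
    lnW = np.array([math.log(e.body_weight) for e in ds])
    T = np.array([e.temperature for e in ds], dtype=float)
    U = np.array([e.rel_speed for e in ds], dtype=float)
    lny = np.array([math.log(e.mo2) for e in ds])
    cols = {"lnW": lnW, "T": T, "U": U}
    for name, col in cols.items():
        if np.ptp(col) == 0.0:
            raise EstimationError(f"collinear: {_PRED_NAMES[name]}")
    X = np.column_stack([np.ones_like(lnW), lnW, T, U])
    if np.linalg.matrix_rank(X) < 4:
        raise EstimationError("collinear: design matrix is rank deficient")
    res = sm.OLS(lny, X).fit()
    i, bb, ct, cu = res.params
    return CoefficientSet(a=math.exp(i), b=float(bb), c=math.exp(ct), d=math.exp(cu))


# ---------------------------------------------------------------------------
# marginal likelihood

def marginal_loglik(
    coefs: CoefficientSet,
    sigma_study: float,
    sigma_resid: float,
    ds: Dataset,
    gamma: float = 0.0,
    interaction: str | None = None,
) -> float:
    """Exact Gaussian marginal log-likelihood of the random-intercept model."""
    if sigma_resid <= 0:
        raise ValueError("sigma_resid must be > 0")
    if sigma_study < 0:
        raise ValueError("sigma_study must be >= 0")
    prob = _Problem(ds, interaction)
    ll, _ = prob.loglik_and_grad(
        coefs.a, coefs.b, math.log(coefs.c), math.log(coefs.d), gamma, sigma_study, sigma_resid
    )
    return float(ll)


# ---------------------------------------------------------------------------
# stage 2

@dataclass
class FitResult:
    """Stage-2 maximum-likelihood fit of the nonlinear mixed-effects model."""

    coefficients: CoefficientSet
    se: dict[str, float]  # natural-scale SEs for a, b, c, d
    vcov: np.ndarray  # 4x4 natural-scale (a, b, c, d) covariance
    sigma_study: float
    sigma_resid: float
    loglik: float
    n_entries: int
    n_studies: int
    converged: bool
    n_iter: int
    start_values: CoefficientSet
    param_names: list[str] = field(default_factory=list)
    params_opt: np.ndarray | None = None  # optimisation-scale parameter vector
    se_opt: np.ndarray | None = None
    vcov_opt: np.ndarray | None = None  # full optimisation-scale covariance
    gamma: float | None = None  # interaction coefficient, if fitted
    se_gamma: float | None = None
    gradient_norm: float = math.nan
    warnings: list[str] = field(default_factory=list)
    interaction: str | None = None

    @property
    def n_parameters(self) -> int:
        return len(self.param_names)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.loglik

    def to_dict(self) -> dict:
        c = self.coefficients
        return {
            "coefficients": {"a": c.a, "b": c.b, "c": c.c, "d": c.d},
            "se": dict(self.se),
            "vcov": np.asarray(self.vcov).tolist(),
            "sigma_study": self.sigma_study,
            "sigma_resid": self.sigma_resid,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_entries": self.n_entries,
            "n_studies": self.n_studies,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "gradient_norm": self.gradient_norm,
            "start_values": dict(zip("abcd", self.start_values.as_tuple())),
            "gamma": self.gamma,
            "se_gamma": self.se_gamma,
            "interaction": self.interaction,
            "warnings": list(self.warnings),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _numerical_hessian(grad_fn, x: np.ndarray) -> np.ndarray:
    """Jacobian of the gradient by central differences, symmetrised."""
    p = len(x)
    H = np.zeros((p, p))
    for k in range(p):
        h = HESSIAN_STEP * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        H[:, k] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_stage2_nlme(
    ds: Dataset,
    start: CoefficientSet,
    *,
    interaction: str | None = None,
    fix_sigma_study: float | None = None,
    max_iter: int = 500,
    multi_start: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the random-intercept nonlinear model.

    Optimises (a, b, ln c, ln d[, gamma], ln sigma_study, ln sigma_resid) by
    L-BFGS-B with the analytic gradient, followed by Newton polishing until
    the gradient infinity-norm over free parameters falls below 1e-6.
    Non-convergence is reported in the result, never raised.
    """
    prob = _Problem(ds, interaction)
    warnings: list[str] = []
    if not all(np.isfinite(start.as_tuple())):
        raise EstimationError("start values must be finite")

    single_study = prob.n_studies < 2
    if single_study and fix_sigma_study is None:
        fix_sigma_study = 0.0
        warnings.append("only one study: sigma_study fixed at 0")
    free_sigma_study = fix_sigma_study is None

    # stage-1 residual SD on the natural scale as the residual start value
    resid0 = np.concatenate(
        [y - _mean_mo2(start, lnW, T, U) for lnW, T, U, P, y in prob.groups]
    )
    se0 = float(np.std(resid0, ddof=1)) if len(resid0) > 1 else 1.0
    se0 = max(se0, 1e-6 * prob.y_scale, 1e-9)
    su_floor = 1e-8 * start.a
    se_floor = max(1e-10, 1e-8 * prob.y_scale)
    sigma_cap = math.log(1e6 * max(1.0, prob.y_scale))  # keeps exp() finite

    names = ["a", "b", "ln_c", "ln_d"]
    x0 = [start.a, start.b, math.log(start.c), math.log(start.d)]
    bounds = [(1e-8, None), (-30.0, 30.0), (-5.0, 5.0), (-5.0, 5.0)]
    if interaction:
        names.append("gamma")
        x0.append(0.0)
        bounds.append((-5.0, 5.0))
    if free_sigma_study:
        names.append("ln_sigma_study")
        x0.append(math.log(max(0.10 * start.a, su_floor)))
        bounds.append((math.log(su_floor), sigma_cap))
    names.append("ln_sigma_resid")
    x0.append(math.log(se0))
    bounds.append((math.log(se_floor), sigma_cap))
    x0 = np.array(x0, dtype=float)

    i_gamma = names.index("gamma") if interaction else None
    i_su = names.index("ln_sigma_study") if free_sigma_study else None
    i_se = names.index("ln_sigma_resid")
    fixed_su = 0.0 if fix_sigma_study is None else float(fix_sigma_study)

    def unpack(x):
        a, b, lnc, lnd = x[0], x[1], x[2], x[3]
        gamma = x[i_gamma] if i_gamma is not None else 0.0
        su = math.exp(x[i_su]) if i_su is not None else fixed_su
        se = math.exp(x[i_se])
        return a, b, lnc, lnd, gamma, su, se

    def neg_and_grad(x):
        a, b, lnc, lnd, gamma, su, se = unpack(x)
        ll, g7 = prob.loglik_and_grad(a, b, lnc, lnd, gamma, su, se)
        if not (np.isfinite(ll) and np.all(np.isfinite(g7))):
            return 1e12, np.zeros(len(x))
        g = list(g7[:4])
        if i_gamma is not None:
            g.append(g7[4])
        if i_su is not None:
            g.append(g7[5])
        g.append(g7[6])
        return -ll, -np.asarray(g)

    def grad_only(x):
        return neg_and_grad(x)[1]

    def free_mask(xv):
        mask = np.ones(len(xv), dtype=bool)
        for k, (lo, hi) in enumerate(bounds):
            if lo is not None and xv[k] <= lo + 1e-9:
                mask[k] = False
            if hi is not None and xv[k] >= hi - 1e-9:
                mask[k] = False
        return mask

    def clamp(xv):
        out = xv.copy()
        for k, (lo, hi) in enumerate(bounds):
            if lo is not None:
                out[k] = max(out[k], lo)
            if hi is not None:
                out[k] = min(out[k], hi)
        return out

    def attempt(xs):
        """L-BFGS-B then Newton polish; returns (x, nll, grad, gnorm, iters)."""
        res = optimize.minimize(
            neg_and_grad, xs, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9, "maxcor": 20},
        )
        iters = int(res.nit)
        x = np.asarray(res.x, dtype=float)
        nll = float(res.fun)
        g = grad_only(x)
        for _ in range(50):
            mask = free_mask(x)
            if np.max(np.abs(g[mask]), initial=0.0) < GRADIENT_TOL:
                break
            H = _numerical_hessian(grad_only, x)
            try:
                step = np.linalg.solve(H[np.ix_(mask, mask)], -g[mask])
            except np.linalg.LinAlgError:
                break
            full = np.zeros_like(x)
            full[mask] = step
            t, improved = 1.0, False
            for _ls in range(30):
                x_new = clamp(x + t * full)
                f_new, g_new = neg_and_grad(x_new)
                if f_new <= nll + 1e-12 * max(1.0, abs(nll)) and np.isfinite(f_new):
                    x, nll, g = x_new, float(f_new), g_new
                    improved = True
                    break
                t *= 0.5
            iters += 1
            if not improved:
                break
        mask = free_mask(x)
        gnorm = float(np.max(np.abs(g[mask]), initial=0.0))
        return x, nll, g, gnorm, iters

    # deterministic restart ladder: the initial start, then jittered copies
    # (guards against the occasional degenerate variance spike)
    n_restarts = max(multi_start, 6)
    rng = np.random.default_rng(0 if seed is None else seed)
    starts = [x0] + [
        clamp(x0 + rng.normal(0.0, 0.15, size=len(x0)) * np.maximum(1.0, np.abs(x0)))
        for _ in range(n_restarts)
    ]
    best = None  # (x, nll, g, gnorm, iters)
    total_iter = 0
    for j, xs in enumerate(starts):
        cand = attempt(xs)
        total_iter += cand[4]
        ok = cand[3] < GRADIENT_TOL
        if best is None:
            best = cand
        else:
            best_ok = best[3] < GRADIENT_TOL
            if (ok and not best_ok) or (ok == best_ok and cand[1] < best[1] - 1e-9):
                best = cand
        # stop early once the plain start converged; keep trying otherwise
        if j == 0 and ok and multi_start == 0:
            break
    x, nll, g, gnorm, _ = best
    mask = free_mask(x)
    converged = bool(np.isfinite(nll)) and gnorm < GRADIENT_TOL
    if not converged:
        warnings.append(f"gradient norm {gnorm:.3g} above tolerance {GRADIENT_TOL:g}")

    a, b, lnc, lnd, gamma, su, se_ = unpack(x)
    coefs = CoefficientSet(a=a, b=b, c=math.exp(lnc), d=math.exp(lnd))

    # observed information -> covariance on the optimisation scale
    H = _numerical_hessian(grad_only, x)
    p = len(x)
    vcov_opt = np.full((p, p), np.nan)
    try:
        vcov_free = np.linalg.inv(H[np.ix_(mask, mask)])
    except np.linalg.LinAlgError:
        vcov_free = np.linalg.pinv(H[np.ix_(mask, mask)])
        warnings.append("observed information singular; pseudo-inverse used for vcov")
    idx = np.where(mask)[0]
    vcov_opt[np.ix_(idx, idx)] = vcov_free
    se_opt = np.sqrt(np.clip(np.diag(vcov_opt), 0.0, None))

    # delta method: (a, b, ln c, ln d) -> (a, b, c, d)
    J = np.diag([1.0, 1.0, coefs.c, coefs.d])
    block = vcov_opt[:4, :4]
    vcov_nat = J @ np.where(np.isnan(block), 0.0, block) @ J.T
    se_nat = {
        "a": float(se_opt[0]),
        "b": float(se_opt[1]),
        "c": float(coefs.c * se_opt[2]),
        "d": float(coefs.d * se_opt[3]),
    }

    return FitResult(
        coefficients=coefs,
        se=se_nat,
        vcov=vcov_nat,
        sigma_study=float(su),
        sigma_resid=float(se_),
        loglik=float(-nll),
        n_entries=prob.n_entries,
        n_studies=prob.n_studies,
        converged=converged,
        n_iter=total_iter,
        start_values=start,
        param_names=names,
        params_opt=x,
        se_opt=se_opt,
        vcov_opt=vcov_opt,
        gamma=float(gamma) if interaction else None,
        se_gamma=float(se_opt[i_gamma]) if interaction else None,
        gradient_norm=gnorm,
        warnings=warnings,
        interaction=interaction,
    )


# ---------------------------------------------------------------------------
# interaction screening

@dataclass
class InteractionReport:
    """LRT/AIC screen of the three candidate two-way product terms."""

    candidates: dict[str, dict]  # term -> {delta_loglik, lrt_p, delta_aic, gamma, evaluable}
    retained: list[str]
    alpha: float

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "candidates": self.candidates, "retained": list(self.retained)}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def screen_interactions(ds: Dataset, base: FitResult, alpha: float = 0.05) -> InteractionReport:
    """Evaluate each two-way product term against the base fit.

    A candidate passes when its likelihood-ratio p-value is below ``alpha``
    and its AIC improves by more than 2. If several pass, the best is retained
    only when its AIC beats the runner-up by more than 2; a tie without a
    clear winner retains nothing.
    """
    if not base.converged:
        raise EstimationError("base fit did not converge; cannot screen interactions")
    candidates: dict[str, dict] = {}
    passing: list[tuple[str, float]] = []  # (term, delta_aic)
    for term in INTERACTION_TERMS:
        fit = fit_stage2_nlme(
            ds,
            base.coefficients,
            interaction=term,
            fix_sigma_study=None if base.n_studies > 1 else 0.0,
        )
        if not fit.converged:
            candidates[term] = {"evaluable": False}
            continue
        d_ll = fit.loglik - base.loglik
        lrt = max(0.0, 2.0 * d_ll)
        p = float(stats.chi2.sf(lrt, df=1))
        d_aic = fit.aic - base.aic
        candidates[term] = {
            "evaluable": True,
            "delta_loglik": float(d_ll),
            "lrt_p": p,
            "delta_aic": float(d_aic),
            "gamma": fit.gamma,
            "se_gamma": fit.se_gamma,
        }
        if p < alpha and d_aic < -2.0:
            passing.append((term, d_aic))
    if len(passing) <= 1:
        retained = [t for t, _ in passing]
    else:
        passing.sort(key=lambda kv: kv[1])
        best, runner = passing[0], passing[1]
        retained = [best[0]] if best[1] <= runner[1] - 2.0 else []
    return InteractionReport(candidates=candidates, retained=retained, alpha=alpha)


# ---------------------------------------------------------------------------
# confidence intervals

def wald_confint(fit: FitResult, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald intervals on the optimisation scale, back-transformed.

    a and b are estimated on the natural scale; c and d as ln c, ln d, so
    their intervals are exponentiated (always positive, contain the point
    estimate).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if not fit.converged:
        raise EstimationError("fit did not converge; intervals unavailable")
    z = float(stats.norm.ppf(0.5 * (1.0 + level)))
    c = fit.coefficients
    se = fit.se_opt
    lnc, lnd = math.log(c.c), math.log(c.d)
    out = {
        "a": (c.a - z * se[0], c.a + z * se[0]),
        "b": (c.b - z * se[1], c.b + z * se[1]),
        "c": (math.exp(lnc - z * se[2]), math.exp(lnc + z * se[2])),
        "d": (math.exp(lnd - z * se[3]), math.exp(lnd + z * se[3])),
    }
    return {k: (float(lo), float(hi)) for k, (lo, hi) in out.items()}
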