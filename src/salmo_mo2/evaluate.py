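"""Model evaluation: predictions, fit diagnostics, legacy comparison, Q10.

All quantities are computed from fixed-effect (population-level) predictions
by default; conditional predictions that add the estimated study-level
intercept deviations are available for diagnostics where a fitted
:class:`~salmo_mo2.estimate.FitResult` is supplied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .dataset import Dataset
from .estimate import CoefficientSet, FitResult, LEGACY_MODEL

__all__ = [
    "DiagnosticsReport",
    "ContrastReport",
    "PredictionGrid",
    "predict_fixed",
    "diagnostics",
    "compare_models",
    "q10",
    "coefficient_contrast",
    "prediction_grid",
    "coefficient_table",
]


def predict_fixed(coefs: CoefficientSet, W, T, U):
    """Population-level MO2 = a * W^b * c^T * d^U (mg O2 kg^-1 h^-1).

    Accepts scalars or broadcastable arrays; W must be strictly positive.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("body weight W must be > 0")
    out = coefs.a * W**coefs.b * coefs.c ** np.asarray(T, dtype=float) * coefs.d ** np.asarray(U, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class DiagnosticsReport:
    """Goodness of fit of a coefficient set against a dataset."""

    r2: float
    adj_r2: float | None  # None (flagged) when n <= p + 1
    rmse: float
    n: int
    n_predictors: int
    residuals: np.ndarray
    std_residuals: np.ndarray
    qq_pairs: np.ndarray  # (n, 2): theoretical normal vs sorted standardised
    prediction_level: str = "population"

    def to_dict(self, include_residuals: bool = True) -> dict:
        out = {
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "n": self.n,
            "n_predictors": self.n_predictors,
            "prediction_level": self.prediction_level,
        }
        if include_residuals:
            out["residuals"] = np.asarray(self.residuals).tolist()
            out["std_residuals"] = np.asarray(self.std_residuals).tolist()
            out["qq_pairs"] = np.asarray(self.qq_pairs).tolist()
        return out

    def to_json(self, path: str | Path | None = None, include_residuals: bool = True) -> str:
        text = json.dumps(self.to_dict(include_residuals), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _fitted_values(model, ds: Dataset, prediction_level: str) -> np.ndarray:
    coefs = model.coefficients if isinstance(model, FitResult) else model
    W = np.array([e.body_weight for e in ds])
    T = np.array([e.temperature for e in ds])
    U = np.array([e.rel_speed for e in ds])
    fitted = predict_fixed(coefs, W, T, U)
    if prediction_level == "conditional":
        if not isinstance(model, FitResult):
            raise ValueError("conditional predictions need a FitResult")
        blups = _study_blups(model, ds)
        x = fitted / coefs.a  # basis values W^b c^T d^U
        u = np.array([blups.get(e.study_id, 0.0) for e in ds])
        fitted = fitted + u * x
    elif prediction_level != "population":
        raise ValueError(f"unknown prediction_level: {prediction_level}")
    return np.atleast_1d(fitted)


def _study_blups(fit: FitResult, ds: Dataset) -> dict[str, float]:
    """Posterior-mean study intercept deviations u_i given the fit."""
    coefs = fit.coefficients
    v, s2 = fit.sigma_study**2, fit.sigma_resid**2
    out = {}
    for sid in {e.study_id for e in ds}:
        sub = [e for e in ds if e.study_id == sid]
        W = np.array([e.body_weight for e in sub])
        T = np.array([e.temperature for e in sub])
        U = np.array([e.rel_speed for e in sub])
        y = np.array([e.mo2 for e in sub])
        x = predict_fixed(coefs, W, T, U) / coefs.a
        r = y - coefs.a * x
        out[sid] = float(v * (x @ r) / (s2 + v * float(x @ x)))
    return out


def diagnostics(
    model: FitResult | CoefficientSet,
    ds: Dataset,
    prediction_level: str = "population",
    n_predictors: int = 3,
    rmse_denominator: str = "n",
) -> DiagnosticsReport:
    """R^2, adjusted R^2 (p = 3 predictors), RMSE and residual diagnostics.

    Residuals are standardised by the fitted residual SD when ``model`` is a
    :class:`FitResult`, otherwise by the RMSE. Q-Q pairs compare sorted
    standardised residuals with standard-normal quantiles at (i - 0.5)/n.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    y = np.array([e.mo2 for e in ds])
    fitted = _fitted_values(model, ds, prediction_level)
    resid = y - fitted
    n = len(y)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    p = n_predictors
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else None
    denom = n if rmse_denominator == "n" else n - p
    rmse = math.sqrt(sse / denom)
    sigma = model.sigma_resid if isinstance(model, FitResult) else (rmse if rmse > 0 else 1.0)
    std = resid / sigma if sigma > 0 else np.zeros_like(resid)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = np.column_stack([theo, np.sort(std)])
    return DiagnosticsReport(
        r2=float(r2),
        adj_r2=None if adj_r2 is None else float(adj_r2),
        rmse=float(rmse),
        n=n,
        n_predictors=p,
        residuals=resid,
        std_residuals=std,
        qq_pairs=qq,
        prediction_level=prediction_level,
    )


def compare_models(
    ds: Dataset,
    candidate: CoefficientSet | FitResult,
    legacy: CoefficientSet = LEGACY_MODEL,
) -> tuple[DiagnosticsReport, DiagnosticsReport]:
    """Evaluate candidate and legacy fixed-effect predictions on one dataset.

    The legacy set is scored as published, without refitting.
    """
    cand_coefs = candidate.coefficients if isinstance(candidate, FitResult) else candidate
    return diagnostics(cand_coefs, ds), diagnostics(legacy, ds)


def q10(coefs: CoefficientSet | float) -> float:
    """Q10 = c^10: multiplicative MO2 change per 10 °C rise."""
    c = coefs.c if isinstance(coefs, CoefficientSet) else float(coefs)
    if c <= 0:
        raise ValueError("temperature coefficient c must be > 0")
    return float(c**10)


@dataclass
class ContrastReport:
    """How one coefficient set reshapes the MO2 surface relative to another."""

    intercept_pct_change: float  # % change of a (vertical shift of the curve)
    b_abs_change: float  # absolute change in the allometric exponent
    q10_old: float
    q10_new: float
    q10_sensitivity_pct: float  # relative change of the per-10 °C % rise
    d_pct_change: float  # % change of the speed multiplier

    def to_dict(self) -> dict:
        return {
            "intercept_pct_change": self.intercept_pct_change,
            "b_abs_change": self.b_abs_change,
            "q10_old": self.q10_old,
            "q10_new": self.q10_new,
            "q10_sensitivity_pct": self.q10_sensitivity_pct,
            "d_pct_change": self.d_pct_change,
        }


def coefficient_contrast(
    old: CoefficientSet,
    new: CoefficientSet,
    q10_old: float | None = None,
    q10_new: float | None = None,
) -> ContrastReport:
    """Interpretable contrasts between two coefficient sets.

    The temperature-sensitivity contrast compares the percentage MO2 rise per
    10 °C, (Q10 - 1), between the two sets; explicit Q10 overrides allow
    working from rounded published values.
    """
    qo = q10(old) if q10_old is None else float(q10_old)
    qn = q10(new) if q10_new is None else float(q10_new)
    return ContrastReport(
        intercept_pct_change=100.0 * (new.a / old.a - 1.0),
        b_abs_change=new.b - old.b,
        q10_old=qo,
        q10_new=qn,
        q10_sensitivity_pct=100.0 * ((qn - 1.0) - (qo - 1.0)) / (qo - 1.0),
        d_pct_change=100.0 * (new.d / old.d - 1.0),
    )


@dataclass
class PredictionGrid:
    """Predicted MO2 along one axis with a 95 % delta-method band."""

    axis: str  # "W" | "T" | "U"
    values: np.ndarray
    held: dict[str, float]
    predicted: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    level: float
    bands_available: bool

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "values": self.values.tolist(),
            "held": dict(self.held),
            "predicted": self.predicted.tolist(),
            "lower": None if self.lower is None else self.lower.tolist(),
            "upper": None if self.upper is None else self.upper.tolist(),
            "level": self.level,
            "bands_available": self.bands_available,
        }

    def to_frame(self):
        import pandas as pd

        data = {self.axis: self.values, "mo2": self.predicted}
        if self.bands_available:
            data["lower"] = self.lower
            data["upper"] = self.upper
        return pd.DataFrame(data)


def prediction_grid(
    fit: FitResult,
    axis: str,
    grid: tuple[float, float, int],
    held: dict[str, float],
    level: float = 0.95,
) -> PredictionGrid:
    """Prediction curve along one axis, others held fixed.

    The confidence band is built by the delta method on ln(MO2): with
    gradient g = (1/a, ln W, T, U) with respect to (a, b, ln c, ln d),
    var(ln MO2) = g' Sigma g on the optimisation scale, and the band is
    exponentiated so it stays positive and contains the point prediction.
    """
    if axis not in ("W", "T", "U"):
        raise ValueError("axis must be one of W, T, U")
    lo, hi, n = grid
    values = np.linspace(lo, hi, int(n))
    point = {"W": held.get("W"), "T": held.get("T"), "U": held.get("U")}
    coords = {k: np.full_like(values, v, dtype=float) for k, v in point.items() if k != axis}
    coords[axis] = values
    coefs = fit.coefficients
    pred = predict_fixed(coefs, coords["W"], coords["T"], coords["U"])

    vcov = None if fit.vcov_opt is None else fit.vcov_opt[:4, :4]
    if vcov is None or np.any(~np.isfinite(vcov)):
        return PredictionGrid(axis, values, {k: float(v) for k, v in point.items() if k != axis},
                              np.atleast_1d(pred), None, None, level, False)
    z = float(stats.norm.ppf(0.5 * (1.0 + level)))
    G = np.column_stack([
        np.full_like(values, 1.0 / coefs.a),
        np.log(coords["W"]),
        coords["T"],
        coords["U"],
    ])
    var_ln = np.einsum("ij,jk,ik->i", G, vcov, G)
    sd_ln = np.sqrt(np.clip(var_ln, 0.0, None))
    lower = pred * np.exp(-z * sd_ln)
    upper = pred * np.exp(z * sd_ln)
    return PredictionGrid(
        axis=axis,
        values=values,
        held={k: float(v) for k, v in point.items() if k != axis},
        predicted=np.atleast_1d(pred),
        lower=lower,
        upper=upper,
        level=level,
        bands_available=True,
    )


def coefficient_table(rows: list[tuple[str, FitResult | CoefficientSet, DiagnosticsReport]]) -> str:
    """Plain-text comparison table: coefficients (± SE), adjusted R^2, RMSE."""
    lines = [
        f"{'model':<34}{'a':>16}{'b':>16}{'c':>16}{'d':>16}{'adj R2':>9}{'RMSE':>9}"
    ]
    for label, model, diag in rows:
        if isinstance(model, FitResult):
            c, se = model.coefficients, model.se
            cells = [f"{getattr(c, k):.2f} ± {se[k]:.3f}" for k in "abcd"]
        else:
            cells = [f"{getattr(model, k):.2f}" for k in "abcd"]
        adj = "n/a" if diag.adj_r2 is None else f"{diag.adj_r2:.2f}"
        lines.append(f"{label:<34}" + "".join(f"{v:>16}" for v in cells) + f"{adj:>9}{diag.rmse:>9.2f}")
    return "\n".join(lines)
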