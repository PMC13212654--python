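"""Guardrailed end-user prediction with extrapolation flags.

The model was fitted on 0.205–3.38 kg, 3–18 °C and 0.31–2.84 BL s^-1 in
normoxia. Outside those core ranges some extrapolations are physiologically
defensible (allometric scaling to smaller/larger fish, the shallow exponential
down to 0 °C, speeds down to rest) while others are known to overestimate
(above 18 °C the thermal plateau sets in; above ~80-90 % of the critical
swimming speed anaerobic metabolism takes over). Requests below 0 °C (plasma
freezing) or above 23 °C (upper thermal tolerance) are refused outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .estimate import CoefficientSet, REVISED_MODEL
from .evaluate import predict_fixed

__all__ = [
    "GuardrailError",
    "PredictionRequest",
    "PredictionResult",
    "CORE_RANGES",
    "convert_speed",
    "speed_from_relative",
    "predict_guarded",
]

#: Biological ranges of the refined fitting dataset (per-axis core validity).
CORE_RANGES = {"W": (0.205, 3.38), "T": (3.0, 18.0), "U": (0.31, 2.84)}
#: Ranges where extrapolation beyond the core is judged reliable.
OK_RANGES = {"W": (0.1, 6.0), "T": (0.0, 18.0), "U": (0.0, 2.84)}
#: Hard refusal bounds on temperature.
T_MIN, T_MAX = 0.0, 23.0


class GuardrailError(ValueError):
    """Prediction refused: the request lies outside the model's validity."""


def convert_speed(speed_cm_s: float, fork_length_cm: float) -> float:
    """Absolute swimming speed (cm/s) to relative speed (body lengths/s)."""
    if fork_length_cm <= 0:
        raise ValueError("fork_length_cm must be > 0")
    return speed_cm_s / fork_length_cm


def speed_from_relative(rel_speed_bl_s: float, fork_length_cm: float) -> float:
    """Inverse of :func:`convert_speed`."""
    if fork_length_cm <= 0:
        raise ValueError("fork_length_cm must be > 0")
    return rel_speed_bl_s * fork_length_cm


@dataclass
class PredictionRequest:
    W: float  # kg
    T: float  # °C
    U: float | None = None  # BL s^-1
    speed_cm_s: float | None = None
    fork_length_cm: float | None = None
    do_saturation: float | None = None  # % of air saturation, optional
    coefficients: CoefficientSet = REVISED_MODEL

    def resolved_speed(self) -> float:
        has_u = self.U is not None
        has_abs = self.speed_cm_s is not None or self.fork_length_cm is not None
        if has_u and has_abs:
            raise ValueError("supply either U or (speed_cm_s, fork_length_cm), not both")
        if has_u:
            return float(self.U)
        if self.speed_cm_s is None or self.fork_length_cm is None:
            raise ValueError("supply either U or both speed_cm_s and fork_length_cm")
        return convert_speed(self.speed_cm_s, self.fork_length_cm)


_MESSAGES = {
    ("W", "extrapolated_ok"): "body weight outside the fitted 0.205-3.38 kg range; "
    "allometric extrapolation between 0.1 and 6 kg is considered reliable",
    ("W", "extrapolated_caution"): "body weight far outside the fitted range; "
    "treat the prediction with caution",
    ("T", "extrapolated_ok"): "temperature below the fitted 3-18 °C range; the shallow "
    "exponential extrapolates smoothly down to 0 °C",
    ("T", "extrapolated_caution"): "temperature above 18 °C: metabolic rate plateaus towards "
    "the upper thermal tolerance, so the prediction is likely only minorly inflated but "
    "should be treated with caution",
    ("U", "extrapolated_ok"): "relative speed below the fitted 0.31-2.84 BL/s range; "
    "exponential extrapolation down to rest (U = 0) is well supported",
    ("U", "extrapolated_caution"): "relative speed above 2.84 BL/s; beyond 80-90 % of the "
    "critical swimming speed anaerobic metabolism takes over and MO2 is overestimated",
    ("O2", "hypoxia_caution"): "oxygen saturation below 100 %: the estimate holds only above "
    "the limiting oxygen saturation, and peak MO2 near the critical swimming speed is "
    "suppressed under hypoxia",
}


@dataclass
class PredictionResult:
    mo2: float  # mg O2 kg^-1 h^-1
    mo2_absolute: float  # mg O2 h^-1 for the whole fish
    flags: set[str]
    axis_flags: dict[str, str]  # per-axis: in_range | extrapolated_ok | extrapolated_caution
    messages: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mo2": self.mo2,
            "mo2_absolute": self.mo2_absolute,
            "flags": sorted(self.flags),
            "axis_flags": dict(self.axis_flags),
            "messages": dict(self.messages),
        }


def _axis_flag(axis: str, value: float) -> str:
    lo, hi = CORE_RANGES[axis]
    if lo <= value <= hi:
        return "in_range"
    olo, ohi = OK_RANGES[axis]
    if olo <= value <= ohi:
        return "extrapolated_ok"
    return "extrapolated_caution"


def predict_guarded(req: PredictionRequest) -> PredictionResult:
    """Predict MO2 with per-axis validity flags; refuse impossible requests."""
    if req.W <= 0:
        raise ValueError("body weight W must be > 0")
    if req.T < T_MIN:
        raise GuardrailError(
            f"temperature {req.T} °C refused: Atlantic salmon cannot survive below 0 °C "
            "(plasma freezing); no prediction is made"
        )
    if req.T > T_MAX:
        raise GuardrailError(
            f"temperature {req.T} °C refused: predictions are capped at 23 °C, near the "
            "upper thermal tolerance where aerobic metabolism plateaus"
        )
    u = req.resolved_speed()
    if u < 0:
        raise ValueError("relative swimming speed U must be >= 0")

    axis_flags = {"W": _axis_flag("W", req.W), "T": _axis_flag("T", req.T), "U": _axis_flag("U", u)}
    flags = set(axis_flags.values())
    messages = {
        axis: _MESSAGES[(axis, f)] for axis, f in axis_flags.items() if f != "in_range"
    }
    if req.do_saturation is not None and req.do_saturation < 100.0:
        flags.add("hypoxia_caution")
        messages["O2"] = _MESSAGES[("O2", "hypoxia_caution")]

    mo2 = predict_fixed(req.coefficients, req.W, req.T, u)
    return PredictionResult(
        mo2=float(mo2),
        mo2_absolute=float(mo2 * req.W),
        flags=flags,
        axis_flags=axis_flags,
        messages=messages,
    )
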