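"""Synthetic group swim-tunnel respirometry datasets.

The generator emulates the statistical structure of the seven-experiment
compilation the coefficient refit rests on: multiplicative mean
MO2 = a * W^b * c^T * d^U, an additive between-study random deviation on the
intercept (a_i = a + u_i, u_i ~ N(0, sigma_study^2)), Gaussian residual noise
(optionally with SD growing proportionally to the mean, mimicking the
heteroscedasticity seen at high fitted values), and "raw" plateau rows for the
filter stage to remove: one treatment group held at 23 °C and, for every
critical-swimming-speed test, a top row at 100 % U_crit whose MO2 sits below
the exponential extrapolation (aerobic plateau).

The default configuration mirrors the study layout of the compiled dataset:
seven studies, 96 raw entries of which exactly 20 violate the model-assumption
filters, leaving 76 refined entries spanning 0.205–3.38 kg, 3–18 °C and
0.31–2.84 BL s^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .dataset import Dataset, RespirometryEntry

__all__ = [
    "StudyConfig",
    "SyntheticTruth",
    "SyntheticConfig",
    "default_truth",
    "default_config",
    "generate_dataset",
    "config_to_yaml",
    "config_from_yaml",
    "write_truth_json",
]

#: MO2 of a plateau row as a fraction of the exponential extrapolation.
PLATEAU_FACTOR = 0.85


@dataclass
class StudyConfig:
    """Layout of one synthetic study: treatment groups x speed ladder."""

    study_id: str
    weights: tuple[float, ...]  # group-mean body weights, kg
    temperatures: tuple[float, ...]  # °C; one treatment group per (weight, T)
    speed_grid: tuple[float, float, int]  # (min, max, n_steps) in BL s^-1
    group_size: int
    n_replicates: int = 3
    ucrit_test: bool = True  # if True, speeds carry pct_ucrit and a 100 % top row exists
    pct_ucrit_top: float = 90.0  # retained top speed as % of group U_crit
    speed_steps_override: dict[float, int] = field(default_factory=dict)  # per-temperature n_steps

    def __post_init__(self) -> None:
        lo, hi, n = self.speed_grid
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        if n < 1:
            raise ValueError("speed_grid n_steps must be >= 1")
        if any(not (0.0 <= t <= 25.0) for t in self.temperatures):
            raise ValueError("temperatures must lie in [0, 25]")
        if not (0 < self.pct_ucrit_top <= 100):
            raise ValueError("pct_ucrit_top must lie in (0, 100]")

    def n_speeds_at(self, temperature: float) -> int:
        return self.speed_steps_override.get(temperature, self.speed_grid[2])


@dataclass
class SyntheticTruth:
    """Generating parameters; after generation also carries the realized study effects."""

    a: float = 79.7  # intercept, mg O2 kg^-1 h^-1 at W=1, T=0, U=0
    b: float = -0.14  # mass-specific allometric exponent
    c: float = 1.04  # per-°C multiplier
    d: float = 1.63  # per-BL s^-1 multiplier
    sigma_study: float = 8.0  # SD of between-study intercept deviation
    sigma_resid: float = 55.0  # residual SD, mg O2 kg^-1 h^-1
    cv_mode: str = "constant"  # "constant" | "proportional"
    gamma_tu: float = 0.0  # optional T x U product term in the log-scale mean
    study_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.d <= 0:
            raise ValueError("a, c and d must be positive")
        if self.sigma_study < 0 or self.sigma_resid < 0:
            raise ValueError("sigma_study and sigma_resid must be >= 0")
        if self.cv_mode not in ("constant", "proportional"):
            raise ValueError(f"unknown cv_mode: {self.cv_mode}")

    def mean(self, W, T, U):
        """Population-level generating mean (no study effect, no noise)."""
        W = np.asarray(W, dtype=float)
        return self.a * W**self.b * self.c**T * self.d**U * np.exp(self.gamma_tu * np.asarray(T) * np.asarray(U))


@dataclass
class SyntheticConfig:
    studies: list[StudyConfig]
    truth: SyntheticTruth
    include_plateau_rows: bool = True
    n_planted_violations: int = 0  # extra rows violating the inclusion criteria
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("need at least one study")


def default_truth() -> SyntheticTruth:
    return SyntheticTruth()


def default_config(seed: int = 0) -> SyntheticConfig:
    """Seven-study layout emulating the compiled respirometry dataset.

    76 refined entries after the model-assumption filters; with plateau rows
    enabled the raw table has 96 entries of which exactly 20 violate the
    filters (one eight-row 23 °C treatment group plus one 100 % U_crit row per
    critical-swim treatment group).
    """
    studies = [
        # temperature-varied study incl. the 23 °C group removed by the filter
        StudyConfig(
            "tempvar_2017", (0.45,), (3.0, 8.0, 13.0, 18.0, 23.0),
            (0.40, 2.66, 5), group_size=10, speed_steps_override={23.0: 7},
        ),
        # size-varied study: smallest and largest fish in the compilation
        StudyConfig("sizevar_2019", (3.38, 0.949, 0.205), (16.0,), (0.31, 2.70, 6), group_size=10),
        StudyConfig("warm_ladder_2022", (0.478,), (18.0,), (0.89, 2.69, 12), group_size=9),
        StudyConfig("fast_ladder_2017", (0.347,), (13.0,), (0.63, 2.84, 8), group_size=15),
        StudyConfig("midsize_2017", (0.821,), (13.0,), (0.46, 1.87, 6), group_size=8),
        StudyConfig("smolt_2018", (0.403,), (13.0,), (0.44, 2.70, 6), group_size=10),
        StudyConfig("grower_2021", (0.667,), (12.0,), (0.78, 2.35, 6), group_size=10),
    ]
    return SyntheticConfig(studies=studies, truth=default_truth(), seed=seed)


def _fork_length_cm(weight_kg: float) -> float:
    # condition factor K = 1.2 g cm^-3 * 100: L = (1e5 * W / 1.2)^(1/3)
    return float((1e5 * weight_kg / 1.2) ** (1.0 / 3.0))


_VIOLATION_CYCLE = [
    ("oxygen_regime", "hypoxia"),
    ("salinity_regime", "brackish"),
    ("acclimation_weeks", 1.0),
    ("health_status", "lice_infested"),
    ("fed_state", "fasted_72h"),
]


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw one synthetic dataset; fully reproducible from ``config.seed``.

    Returns the dataset together with a copy of the truth whose
    ``study_effects`` holds the realized per-study intercept deviations u_i.
    """
    rng = np.random.default_rng(config.seed)
    t = config.truth
    truth = SyntheticTruth(
        a=t.a, b=t.b, c=t.c, d=t.d, sigma_study=t.sigma_study,
        sigma_resid=t.sigma_resid, cv_mode=t.cv_mode, gamma_tu=t.gamma_tu,
        study_effects={s.study_id: float(rng.normal(0.0, t.sigma_study)) for s in config.studies},
    )

    def draw_mo2(mean: float) -> float:
        sd = t.sigma_resid if t.cv_mode == "constant" else t.sigma_resid * mean / t.a
        if sd == 0.0:
            return mean
        val = rng.normal(mean, sd)
        while val <= 0.0:  # truncation by redraw preserves positivity
            val = rng.normal(mean, sd)
        return float(val)

    entries: list[RespirometryEntry] = []
    for study in config.studies:
        u_i = truth.study_effects[study.study_id]
        for w in study.weights:
            for temp in study.temperatures:
                lo, hi, _ = study.speed_grid
                n_speeds = study.n_speeds_at(temp)
                speeds = np.linspace(lo, hi, n_speeds) if n_speeds > 1 else np.array([lo])
                ucrit = hi / (study.pct_ucrit_top / 100.0) if study.ucrit_test else None
                treatment = f"W{w:g}_T{temp:g}"
                row_speeds = list(speeds)
                if config.include_plateau_rows and study.ucrit_test:
                    row_speeds.append(ucrit)
                for speed in row_speeds:
                    at_plateau = study.ucrit_test and config.include_plateau_rows and speed == ucrit
                    mean = (t.a + u_i) * w**t.b * t.c**temp * t.d**speed
                    mean *= float(np.exp(t.gamma_tu * temp * speed))
                    if at_plateau:
                        mean *= PLATEAU_FACTOR
                    if ucrit is None:
                        pct = None
                    elif at_plateau:
                        pct = 100.0
                    else:
                        pct = min(100.0, 100.0 * speed / ucrit)
                    entries.append(
                        RespirometryEntry(
                            study_id=study.study_id,
                            treatment_id=treatment,
                            body_weight=w,
                            fork_length=_fork_length_cm(w),
                            temperature=temp,
                            rel_speed=float(speed),
                            mo2=draw_mo2(mean),
                            pct_ucrit=pct,
                            group_size=study.group_size,
                            n_replicates=study.n_replicates,
                        )
                    )
    # extra rows violating the inclusion criteria, for filter tests
    for k in range(config.n_planted_violations):
        study = config.studies[k % len(config.studies)]
        w = study.weights[0]
        temp = study.temperatures[0]
        field_name, bad_value = _VIOLATION_CYCLE[k % len(_VIOLATION_CYCLE)]
        u_i = truth.study_effects[study.study_id]
        speed = 1.0 + 0.01 * k  # keep keys unique
        mean = (t.a + u_i) * w**t.b * t.c**temp * t.d**speed
        kwargs = dict(
            study_id=study.study_id,
            treatment_id=f"planted_{k}",
            body_weight=w,
            fork_length=_fork_length_cm(w),
            temperature=temp,
            rel_speed=speed,
            mo2=draw_mo2(mean),
            group_size=study.group_size,
            n_replicates=study.n_replicates,
        )
        kwargs[field_name] = bad_value
        entries.append(RespirometryEntry(**kwargs))

    return Dataset(entries, provenance=f"synthetic(seed={config.seed})"), truth


# ---------------------------------------------------------------------------
# serialization

def config_to_yaml(config: SyntheticConfig, path: str | Path | None = None) -> str:
    payload = {
        "seed": config.seed,
        "include_plateau_rows": config.include_plateau_rows,
        "n_planted_violations": config.n_planted_violations,
        "truth": {k: v for k, v in asdict(config.truth).items() if k != "study_effects"},
        "studies": [
            {
                "study_id": s.study_id,
                "weights": list(s.weights),
                "temperatures": list(s.temperatures),
                "speed_grid": list(s.speed_grid),
                "group_size": s.group_size,
                "n_replicates": s.n_replicates,
                "ucrit_test": s.ucrit_test,
                "pct_ucrit_top": s.pct_ucrit_top,
                "speed_steps_override": {str(k): v for k, v in s.speed_steps_override.items()},
            }
            for s in config.studies
        ],
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source: str | Path) -> SyntheticConfig:
    try:
        is_file = Path(str(source)).exists()
    except OSError:  # raw YAML text, not a path
        is_file = False
    text = Path(str(source)).read_text() if is_file else str(source)
    payload = yaml.safe_load(text)
    studies = [
        StudyConfig(
            study_id=s["study_id"],
            weights=tuple(s["weights"]),
            temperatures=tuple(s["temperatures"]),
            speed_grid=tuple(s["speed_grid"]),
            group_size=s["group_size"],
            n_replicates=s.get("n_replicates", 3),
            ucrit_test=s.get("ucrit_test", True),
            pct_ucrit_top=s.get("pct_ucrit_top", 90.0),
            speed_steps_override={float(k): v for k, v in s.get("speed_steps_override", {}).items()},
        )
        for s in payload["studies"]
    ]
    return SyntheticConfig(
        studies=studies,
        truth=SyntheticTruth(**payload["truth"]),
        include_plateau_rows=payload.get("include_plateau_rows", True),
        n_planted_violations=payload.get("n_planted_violations", 0),
        seed=payload.get("seed", 0),
    )


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(truth), indent=2))
    return path
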