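"""Respirometry dataset container, CSV I/O, replicate aggregation and filtering.

One :class:`RespirometryEntry` is a replicate-aggregated group swim-tunnel
observation: a unique combination of study, treatment group, body weight (kg),
water temperature (°C) and relative swimming speed (body lengths per second),
with the mean mass-specific oxygen consumption rate MO2 (mg O2 kg^-1 h^-1)
over the affiliated replicate trials, plus the metadata that the inclusion
criteria are checked against (salinity, oxygen regime, thermal acclimation,
health, feeding state, strain).

Two filter stages are provided:

* :func:`apply_inclusion_criteria` keeps only entries measured under
  commercially representative, methodologically consistent conditions
  (full-strength seawater, normoxia, >= 3 weeks of thermal acclimation,
  healthy fish fed through acclimation and fasted only overnight).
* :func:`apply_model_assumption_filters` removes entries where the
  multiplicative exponential model is known to break down: groups held at or
  above 23 °C (thermal plateau of aerobic metabolism) and speeds at 100 % of
  the group critical swimming speed (anaerobic recruitment plateau).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "RespirometryEntry",
    "Dataset",
    "FilterReport",
    "RangeSummary",
    "DatasetFormatError",
    "DatasetParseError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "aggregate_replicates",
    "apply_inclusion_criteria",
    "apply_model_assumption_filters",
    "summarize",
]

#: Exact header of the canonical CSV representation.
CANONICAL_COLUMNS = [
    "study_id",
    "treatment_id",
    "body_weight_kg",
    "fork_length_cm",
    "temperature_c",
    "rel_speed_bl_s",
    "pct_ucrit",
    "mo2_mg_kg_h",
    "group_size",
    "n_replicates",
    "salinity_regime",
    "oxygen_regime",
    "acclimation_weeks",
    "health_status",
    "fed_state",
    "strain",
]

_NUMERIC_REQUIRED = ["body_weight_kg", "fork_length_cm", "temperature_c", "rel_speed_bl_s", "mo2_mg_kg_h"]


class DatasetFormatError(ValueError):
    """The file does not have the expected tabular shape (e.g. missing column)."""


class DatasetParseError(ValueError):
    """A row holds a value that cannot be parsed or violates an entry invariant."""


class ValidationError(ValueError):
    """Entries are mutually inconsistent (duplicate keys, conflicting temperatures)."""


@dataclass(frozen=True)
class RespirometryEntry:
    """A single replicate-aggregated group respirometry observation."""

    study_id: str
    treatment_id: str
    body_weight: float  # kg, group mean (W)
    fork_length: float  # cm, group mean
    temperature: float  # °C (T)
    rel_speed: float  # body lengths s^-1 (U)
    mo2: float  # mg O2 kg^-1 h^-1 (MO2)
    pct_ucrit: float | None = None  # % of group critical swimming speed
    group_size: int = 1
    n_replicates: int = 1
    salinity_regime: str = "seawater_full"
    oxygen_regime: str = "normoxia"
    acclimation_weeks: float = 4.0
    health_status: str = "healthy"
    fed_state: str = "fed_then_overnight_fast"
    strain: str = "aquagen"

    def __post_init__(self) -> None:
        problems = self.problems()
        if problems:
            raise DatasetParseError("; ".join(problems))

    def problems(self) -> list[str]:
        """Invariant violations as human-readable strings (empty = valid)."""
        out = []
        if not self.body_weight > 0:
            out.append(f"body_weight must be > 0, got {self.body_weight}")
        if not self.fork_length > 0:
            out.append(f"fork_length must be > 0, got {self.fork_length}")
        if not (-2.0 <= self.temperature <= 40.0):
            out.append(f"temperature outside sanity bounds [-2, 40]: {self.temperature}")
        if not self.rel_speed >= 0:
            out.append(f"rel_speed must be >= 0, got {self.rel_speed}")
        if not self.mo2 > 0:
            out.append(f"mo2 must be > 0, got {self.mo2}")
        if self.group_size < 1:
            out.append(f"group_size must be >= 1, got {self.group_size}")
        if self.n_replicates < 1:
            out.append(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.pct_ucrit is not None and not (0.0 < self.pct_ucrit <= 100.0):
            out.append(f"pct_ucrit must lie in (0, 100], got {self.pct_ucrit}")
        return out

    @property
    def key(self) -> tuple:
        return (self.study_id, self.treatment_id, self.body_weight, self.temperature, self.rel_speed)


class Dataset:
    """Ordered collection of unique respirometry entries with provenance."""

    def __init__(self, entries: Iterable[RespirometryEntry], provenance: str = "unknown"):
        self.entries: list[RespirometryEntry] = list(entries)
        self.provenance = provenance
        seen: set[tuple] = set()
        for e in self.entries:
            if e.key in seen:
                raise ValidationError(f"duplicate entry key {e.key}")
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> RespirometryEntry:
        return self.entries[i]

    @property
    def study_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.study_id not in out:
                out.append(e.study_id)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "study_id": e.study_id,
                    "treatment_id": e.treatment_id,
                    "body_weight_kg": e.body_weight,
                    "fork_length_cm": e.fork_length,
                    "temperature_c": e.temperature,
                    "rel_speed_bl_s": e.rel_speed,
                    "pct_ucrit": e.pct_ucrit,
                    "mo2_mg_kg_h": e.mo2,
                    "group_size": e.group_size,
                    "n_replicates": e.n_replicates,
                    "salinity_regime": e.salinity_regime,
                    "oxygen_regime": e.oxygen_regime,
                    "acclimation_weeks": e.acclimation_weeks,
                    "health_status": e.health_status,
                    "fed_state": e.fed_state,
                    "strain": e.strain,
                }
            )
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _entry_from_row(row: Mapping, rownum: int) -> RespirometryEntry:
    def num(col: str) -> float:
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise DatasetParseError(f"row {rownum}: non-numeric or missing value in column '{col}'")
        try:
            return float(v)
        except (TypeError, ValueError):
            raise DatasetParseError(f"row {rownum}: non-numeric value {v!r} in column '{col}'") from None

    pct = row.get("pct_ucrit")
    if pct is not None and isinstance(pct, float) and math.isnan(pct):
        pct = None
    elif pct is not None and str(pct).strip() == "":
        pct = None
    try:
        return RespirometryEntry(
            study_id=str(row["study_id"]),
            treatment_id=str(row["treatment_id"]),
            body_weight=num("body_weight_kg"),
            fork_length=num("fork_length_cm"),
            temperature=num("temperature_c"),
            rel_speed=num("rel_speed_bl_s"),
            mo2=num("mo2_mg_kg_h"),
            pct_ucrit=None if pct is None else float(pct),
            group_size=int(num("group_size")),
            n_replicates=int(num("n_replicates")),
            salinity_regime=str(row["salinity_regime"]),
            oxygen_regime=str(row["oxygen_regime"]),
            acclimation_weeks=num("acclimation_weeks"),
            health_status=str(row["health_status"]),
            fed_state=str(row["fed_state"]),
            strain=str(row["strain"]),
        )
    except DatasetParseError as exc:
        raise DatasetParseError(f"row {rownum}: {exc}" if "row " not in str(exc) else str(exc)) from None


def read_dataset(path: str | Path, format: str = "csv") -> Dataset:
    """Read a canonical respirometry CSV into a :class:`Dataset`.

    Rows are numbered from 1 (first data row) in error messages.
    """
    if format != "csv":
        raise DatasetFormatError(f"unsupported format: {format}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required column(s): {', '.join(missing)}")
    entries = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        entries.append(_entry_from_row(row.to_dict(), i))
    return Dataset(entries, provenance=str(path))


def write_dataset(ds: Dataset, path: str | Path) -> Path:
    """Write the canonical CSV (UTF-8, comma-separated, empty field = missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_dataframe().to_csv(path, index=False)
    return path


@dataclass
class FilterReport:
    """Bookkeeping for one filter pass: what was removed and under which rule."""

    n_in: int
    n_out: int
    removed: list[tuple[tuple, str]] = field(default_factory=list)
    rules_applied: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "removed": [{"key": list(k), "rule": r} for k, r in self.removed],
            "rules_applied": list(self.rules_applied),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def aggregate_replicates(trials: pd.DataFrame | Sequence[Mapping]) -> Dataset:
    """Collapse per-trial records into one entry per treatment/speed combination.

    ``trials`` carries one row per replicate trial with trial-level group-mean
    body weight, fork length and MO2. Rows sharing
    (study_id, treatment_id, rel_speed_bl_s) are replicates of the same
    condition: their weight, length and MO2 are averaged (unweighted) and
    ``n_replicates`` records how many trials were pooled. Water temperature
    is a property of the treatment condition and must agree across replicates.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = pd.DataFrame(list(trials))
    if trials.empty:
        return Dataset([], provenance="aggregated(empty)")
    entries = []
    for (study, treatment, speed), grp in trials.groupby(
        ["study_id", "treatment_id", "rel_speed_bl_s"], sort=False
    ):
        temps = sorted(set(float(t) for t in grp["temperature_c"]))
        if len(temps) > 1:
            raise ValidationError(
                f"inconsistent temperature within key ({study}, {treatment}, U={speed}): {temps}"
            )
        first = grp.iloc[0].to_dict()
        pct_vals = grp.get("pct_ucrit")
        pct = None
        if pct_vals is not None:
            finite = [float(v) for v in pct_vals if v is not None and not pd.isna(v)]
            pct = float(pd.Series(finite).mean()) if finite else None
        entries.append(
            RespirometryEntry(
                study_id=str(study),
                treatment_id=str(treatment),
                body_weight=float(grp["body_weight_kg"].mean()),
                fork_length=float(grp["fork_length_cm"].mean()),
                temperature=temps[0],
                rel_speed=float(speed),
                mo2=float(grp["mo2_mg_kg_h"].mean()),
                pct_ucrit=pct,
                group_size=int(first.get("group_size", 1)),
                n_replicates=len(grp),
                salinity_regime=str(first.get("salinity_regime", "seawater_full")),
                oxygen_regime=str(first.get("oxygen_regime", "normoxia")),
                acclimation_weeks=float(first.get("acclimation_weeks", 4.0)),
                health_status=str(first.get("health_status", "healthy")),
                fed_state=str(first.get("fed_state", "fed_then_overnight_fast")),
                strain=str(first.get("strain", "aquagen")),
            )
        )
    return Dataset(entries, provenance="aggregated")


_INCLUSION_RULES = [
    ("seawater_full", lambda e, p: e.salinity_regime == "seawater_full"),
    ("normoxia", lambda e, p: e.oxygen_regime == "normoxia"),
    ("acclimation", lambda e, p: e.acclimation_weeks >= p["min_acclimation_weeks"]),
    ("healthy", lambda e, p: e.health_status == "healthy"),
    ("fed_state", lambda e, p: e.fed_state == "fed_then_overnight_fast"),
]


def apply_inclusion_criteria(
    ds: Dataset, min_acclimation_weeks: float = 3.0
) -> tuple[Dataset, FilterReport]:
    """Keep entries matching the environmental/husbandry inclusion criteria.

    Each removed entry is attributed to the first rule it violates, in the
    order: full-strength seawater, normoxia, acclimation duration, health,
    feeding state.
    """
    params = {"min_acclimation_weeks": min_acclimation_weeks}
    kept, removed = [], []
    for e in ds:
        for rule, ok in _INCLUSION_RULES:
            if not ok(e, params):
                removed.append((e.key, rule))
                break
        else:
            kept.append(e)
    report = FilterReport(
        n_in=len(ds),
        n_out=len(kept),
        removed=removed,
        rules_applied=[r for r, _ in _INCLUSION_RULES],
    )
    return Dataset(kept, provenance=ds.provenance), report


def apply_model_assumption_filters(
    ds: Dataset, temp_cutoff: float = 23.0, ucrit_cutoff: float = 100.0
) -> tuple[Dataset, FilterReport]:
    """Remove entries where the exponential T and U terms are known to plateau.

    Entries with ``temperature >= temp_cutoff`` go first (thermal plateau near
    upper tolerance); surviving entries with ``pct_ucrit >= ucrit_cutoff`` go
    next (anaerobic recruitment near the critical swimming speed). Entries
    without a recorded ``pct_ucrit`` (sustained-speed tests) are never removed
    by the speed rule.
    """
    kept, removed = [], []
    for e in ds:
        if e.temperature >= temp_cutoff:
            removed.append((e.key, "temp_cutoff"))
        elif e.pct_ucrit is not None and e.pct_ucrit >= ucrit_cutoff:
            removed.append((e.key, "ucrit_cutoff"))
        else:
            kept.append(e)
    report = FilterReport(
        n_in=len(ds),
        n_out=len(kept),
        removed=removed,
        rules_applied=["temp_cutoff", "ucrit_cutoff"],
    )
    return Dataset(kept, provenance=ds.provenance), report


@dataclass
class RangeSummary:
    """Biological ranges and per-study composition of a dataset."""

    n_entries: int
    ranges: dict[str, tuple[float, float]]  # var -> (min, max)
    per_study_entries: dict[str, int]
    per_study_pct: dict[str, float]
    total_fish: int

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "per_study_entries": self.per_study_entries,
            "per_study_pct": self.per_study_pct,
            "total_fish": self.total_fish,
        }


def summarize(ds: Dataset) -> RangeSummary:
    """Min/max of W, T, U and MO2, per-study entry counts and total fish.

    Total fish counts each treatment group once as group_size x n_replicates
    (replicate trials use separate groups of fish; the same group swims the
    whole speed ladder).
    """
    if len(ds) == 0:
        raise ValidationError("cannot summarize an empty dataset")
    df = ds.to_dataframe()
    ranges = {
        "body_weight_kg": (float(df.body_weight_kg.min()), float(df.body_weight_kg.max())),
        "temperature_c": (float(df.temperature_c.min()), float(df.temperature_c.max())),
        "rel_speed_bl_s": (float(df.rel_speed_bl_s.min()), float(df.rel_speed_bl_s.max())),
        "mo2_mg_kg_h": (float(df.mo2_mg_kg_h.min()), float(df.mo2_mg_kg_h.max())),
    }
    counts = {s: int(n) for s, n in df.groupby("study_id", sort=False).size().items()}
    pct = {s: 100.0 * n / len(ds) for s, n in counts.items()}
    fish = int(
        df.drop_duplicates(["study_id", "treatment_id"])
        .apply(lambda r: r.group_size * r.n_replicates, axis=1)
        .sum()
    )
    return RangeSummary(
        n_entries=len(ds),
        ranges=ranges,
        per_study_entries=counts,
        per_study_pct=pct,
        total_fish=fish,
    )
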