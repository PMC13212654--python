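import pytest
from hypothesis import settings

from salmo_mo2 import (
    apply_inclusion_criteria,
    apply_model_assumption_filters,
    default_config,
    generate_dataset,
)
from salmo_mo2.dataset import Dataset, RespirometryEntry
from salmo_mo2.synth import StudyConfig, SyntheticConfig, SyntheticTruth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

TRUTH = {"a": 79.7, "b": -0.14, "c": 1.04, "d": 1.63}


@pytest.fixture(scope="session")
def raw_dataset():
    """Default synthetic raw table: 96 entries incl. plateau rows (seed 1)."""
    ds, truth = generate_dataset(default_config(seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def refined_dataset(raw_dataset):
    """The 76-entry refined table after both filter stages."""
    ds, truth = raw_dataset
    ds1, _ = apply_inclusion_criteria(ds)
    ds2, _ = apply_model_assumption_filters(ds1)
    return ds2, truth


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic dataset on the default grid: mo2 = a W^b c^T d^U exactly."""
    cfg = default_config(seed=0)
    cfg.truth.sigma_study = 0.0
    cfg.truth.sigma_resid = 0.0
    cfg.include_plateau_rows = False
    ds, truth = generate_dataset(cfg)
    return ds, truth


@pytest.fixture()
def single_study_config():
    """One study varying all of W, T and U (stage-1 identifiable)."""
    study = StudyConfig(
        "solo", (0.3, 0.6, 1.2), (6.0, 12.0, 18.0), (0.5, 2.5, 3),
        group_size=8, ucrit_test=False,
    )
    return SyntheticConfig([study], SyntheticTruth(), include_plateau_rows=False, seed=0)


@pytest.fixture()
def toy_two_study():
    """Tiny 2-study x 3-entry dataset with hand-set values."""
    rows = {
        "s1": [(0.5, 10.0, 1.0, 300.0), (0.5, 10.0, 2.0, 420.0), (0.5, 12.0, 1.5, 380.0)],
        "s2": [(1.2, 8.0, 0.8, 250.0), (1.2, 8.0, 1.8, 360.0), (1.2, 14.0, 1.2, 330.0)],
    }
    entries = [
        RespirometryEntry(sid, f"g{i}", w, 35.0, t, u, y)
        for sid, data in rows.items()
        for i, (w, t, u, y) in enumerate(data)
    ]
    return Dataset(entries, provenance="toy")


def make_entry(**kwargs):
    base = dict(
        study_id="s", treatment_id="t", body_weight=0.5, fork_length=35.0,
        temperature=12.0, rel_speed=1.0, mo2=300.0,
    )
    base.update(kwargs)
    return RespirometryEntry(**base)
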