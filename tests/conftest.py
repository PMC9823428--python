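import numpy as np
import pandas as pd
import pytest

from heinvs import (
    COMPONENTS,
    TIMEPOINTS,
    DietaryRecord,
    FoodEntry,
    ReferenceTable,
    TrialDataset,
)


@pytest.fixture(scope="session")
def refs() -> ReferenceTable:
    return ReferenceTable.default()


def make_diary(
    daily_amounts: dict[str, float],
    subject_id: str = "S1",
    timepoint: str = "t0",
    energy_per_gram: float = 1.0,
    beverage_components: tuple[str, ...] = ("beverages", "alcohol"),
    n_days: int = 7,
) -> DietaryRecord:
    """Constant diary: the same component amounts logged on every day."""
    entries = []
    for day in range(1, n_days + 1):
        for comp, amount in daily_amounts.items():
            is_bev = comp in beverage_components
            entries.append(
                FoodEntry(
                    subject_id=subject_id,
                    timepoint=timepoint,
                    day=day,
                    component=comp,
                    amount=amount,
                    energy=0.0 if is_bev else amount * energy_per_gram,
                    is_beverage=is_bev,
                )
            )
    return DietaryRecord(subject_id, timepoint, entries)


@pytest.fixture
def diary_factory():
    return make_diary


def panel_from_values(
    values: dict[str, np.ndarray], groups: list[str]
) -> TrialDataset:
    """Build a TrialDataset from per-variable (n_subjects, 4) value arrays."""
    n = len(groups)
    subjects = [f"S{i:04d}" for i in range(n)]
    rows = []
    for var, arr in values.items():
        arr = np.asarray(arr, dtype=float)
        assert arr.shape == (n, 4)
        for i in range(n):
            for t, tp in enumerate(TIMEPOINTS):
                rows.append((subjects[i], groups[i], tp, var, arr[i, t]))
    return TrialDataset(
        pd.DataFrame(
            rows, columns=["subject_id", "group", "timepoint", "variable", "value"]
        )
    )


@pytest.fixture
def panel_factory():
    return panel_from_values


def random_score_vector(rng: np.random.Generator, refs: ReferenceTable) -> dict[str, float]:
    return {c: rng.uniform(0.0, refs[c].max_points) for c in COMPONENTS}
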