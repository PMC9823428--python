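"""Data model and I/O for 7-day food diaries and the long-format trial panel.

Two plain-text interchange formats are used throughout the package:

* **Diary CSV** — one logged food item per row with columns
  ``subject_id, group, timepoint, day, component, amount_g, energy_kcal,
  is_beverage``.  Items arrive already assigned to one of the ten index
  components (or ``other``); food-name matching is out of scope.
* **Trial table CSV** — long format with columns
  ``subject_id, group, timepoint, variable, value`` where an empty ``value``
  cell is an explicitly missing observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Measurement occasions: baseline, end of the 12-week programme, and the
#: 6- and 12-month follow-ups.
TIMEPOINTS: tuple[str, ...] = ("t0", "t1", "t2", "t3")

#: The ten food-group components of the index, in reporting order.
COMPONENTS: tuple[str, ...] = (
    "vegetables",
    "fruits",
    "grains",
    "dairy",
    "fish",
    "beverages",
    "eggs",
    "spreadable_fats",
    "alcohol",
    "meat",
)

OTHER_LABEL = "other"
VALID_LABELS: frozenset[str] = frozenset(COMPONENTS) | {OTHER_LABEL}

GROUPS: tuple[str, str] = ("intervention", "control")

#: Outcome-panel vocabulary: total score, the ten component scores, the two
#: dietary summaries and the anthropometric / cardiometabolic variables.
PANEL_VARIABLES: tuple[str, ...] = (
    ("hei_nvs_total",)
    + COMPONENTS
    + (
        "energy_density",
        "energy_intake",
        "body_weight",
        "bmi",
        "waist_circumference",
        "fat_mass",
        "fat_free_mass",
        "total_cholesterol",
        "hdl",
        "ldl",
        "fasting_glucose",
        "hba1c",
        "systolic_bp",
        "diastolic_bp",
    )
)

DIARY_COLUMNS = (
    "subject_id",
    "group",
    "timepoint",
    "day",
    "component",
    "amount_g",
    "energy_kcal",
    "is_beverage",
)

TRIAL_COLUMNS = ("subject_id", "group", "timepoint", "variable", "value")


class ValidationError(ValueError):
    """Raised when an input violates the documented data contract."""


@dataclass(frozen=True)
class FoodEntry:
    """One logged food item of a 7-day diary.

    Amounts are grams; beverages and alcohol use grams with an assumed
    density of 1 g/mL.  ``component`` must be one of the ten index
    components or ``"other"``.
    """

    subject_id: str
    timepoint: str
    day: int
    component: str
    amount: float
    energy: float
    is_beverage: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if self.component not in VALID_LABELS:
            raise ValidationError(
                f"unknown component label {self.component!r}; "
                f"expected one of {sorted(VALID_LABELS)}"
            )
        if not 1 <= int(self.day) <= 7:
            raise ValidationError(f"day must be in 1..7, got {self.day}")
        if self.amount < 0:
            raise ValidationError(f"negative amount {self.amount} g")
        if self.energy < 0:
            raise ValidationError(f"negative energy {self.energy} kcal")


@dataclass
class DietaryRecord:
    """A single subject-timepoint food diary (nominally seven days)."""

    subject_id: str
    timepoint: str
    entries: list[FoodEntry] = field(default_factory=list)
    group: str | None = None

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.subject_id != self.subject_id or e.timepoint != self.timepoint:
                raise ValidationError(
                    f"entry ({e.subject_id}, {e.timepoint}) does not belong to "
                    f"record ({self.subject_id}, {self.timepoint})"
                )

    @property
    def n_days(self) -> int:
        """Number of distinct diary days with at least one entry."""
        return len({e.day for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [e.subject_id for e in self.entries],
                "group": self.group,
                "timepoint": [e.timepoint for e in self.entries],
                "day": [e.day for e in self.entries],
                "component": [e.component for e in self.entries],
                "amount_g": [e.amount for e in self.entries],
                "energy_kcal": [e.energy for e in self.entries],
                "is_beverage": [e.is_beverage for e in self.entries],
            }
        )


def mean_daily_amounts(record: DietaryRecord) -> dict[str, float]:
    """Mean grams/day per component over the diary's observed days.

    Components absent from the diary map to 0.  The divisor is the number
    of distinct days present, so a short (non-7-day) diary is averaged over
    its observed days.
    """
    n_days = record.n_days
    if n_days == 0:
        raise ValidationError(
            f"record ({record.subject_id}, {record.timepoint}) has no diary days"
        )
    totals = dict.fromkeys(COMPONENTS + (OTHER_LABEL,), 0.0)
    for e in record.entries:
        totals[e.component] += e.amount
    return {c: t / n_days for c, t in totals.items()}


def _records_from_frame(
    df: pd.DataFrame, *, require_seven_days: bool, source: str
) -> list[DietaryRecord]:
    records: list[DietaryRecord] = []
    for (sid, tp), chunk in df.groupby(["subject_id", "timepoint"], sort=True):
        group = None
        if "group" in chunk.columns and chunk["group"].notna().any():
            groups = set(chunk["group"].dropna().astype(str))
            if len(groups) > 1:
                raise ValidationError(
                    f"{source}: subject {sid!r} carries conflicting groups {sorted(groups)}"
                )
            group = groups.pop()
        entries = [
            FoodEntry(
                subject_id=str(sid),
                timepoint=str(tp),
                day=int(row.day),
                component=str(row.component),
                amount=float(row.amount_g),
                energy=float(row.energy_kcal),
                is_beverage=bool(row.is_beverage),
            )
            for row in chunk.itertuples()
        ]
        rec = DietaryRecord(str(sid), str(tp), entries, group=group)
        if rec.n_days != 7:
            msg = (
                f"{source}: diary ({sid}, {tp}) covers {rec.n_days} days, not 7"
            )
            if require_seven_days:
                raise ValidationError(msg)
            logger.warning("%s; averaging over observed days", msg)
        records.append(rec)
    return records


def read_food_records(
    path: str | Path, *, require_seven_days: bool = True
) -> list[DietaryRecord]:
    """Read a diary CSV into :class:`DietaryRecord` objects.

    Entries are grouped by (subject, timepoint); component labels are
    validated against the closed vocabulary and offending rows are named in
    the error.  An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("diary file %s contains no entries", path)
        return []
    missing = [c for c in DIARY_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise ValidationError(f"{path}: missing diary columns {missing}")
    bad = ~df["component"].astype(str).isin(VALID_LABELS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {i + 2}: unknown component label "
            f"{df['component'].iloc[i]!r}"
        )
    for col in ("amount_g", "energy_kcal"):
        neg = df[col].astype(float) < 0
        if neg.any():
            i = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValidationError(f"{path}: row {i + 2}: negative {col}")
    return _records_from_frame(
        df, require_seven_days=require_seven_days, source=str(path)
    )


def write_food_records(records: Iterable[DietaryRecord], path: str | Path) -> None:
    """Write diaries to the diary CSV dialect (inverse of ``read_food_records``)."""
    frames = [r.to_frame() for r in records]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(DIARY_COLUMNS))
    )
    out.to_csv(path, index=False)


class TrialDataset:
    """Long-format subject × timepoint × variable outcome panel.

    Wraps a tidy :class:`pandas.DataFrame` with columns
    ``subject_id, group, timepoint, variable, value`` (``NaN`` = missing)
    and enforces the panel contract: no duplicate cells, one group per
    subject, known variables/timepoints, and a baseline row set for every
    subject.
    """

    def __init__(self, data: pd.DataFrame, *, allow_extra_variables: bool = False):
        df = data.copy()
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trial table lacks columns {missing}")
        df = df.loc[:, list(TRIAL_COLUMNS)]
        df["subject_id"] = df["subject_id"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")

        bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
        if bad_tp.any():
            raise ValidationError(
                f"unknown timepoints {sorted(df.loc[bad_tp, 'timepoint'].unique())}"
            )
        bad_grp = ~df["group"].isin(GROUPS)
        if bad_grp.any():
            raise ValidationError(
                f"unknown groups {sorted(df.loc[bad_grp, 'group'].unique())}"
            )
        if not allow_extra_variables:
            bad_var = ~df["variable"].isin(PANEL_VARIABLES)
            if bad_var.any():
                raise ValidationError(
                    f"unknown variables {sorted(df.loc[bad_var, 'variable'].unique())}"
                )
        dup = df.duplicated(subset=["subject_id", "timepoint", "variable"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValidationError(
                "duplicate cell for "
                f"({row.subject_id}, {row.timepoint}, {row.variable})"
            )
        n_groups = df.groupby("subject_id")["group"].nunique()
        if (n_groups > 1).any():
            sid = n_groups.index[n_groups > 1][0]
            raise ValidationError(f"subject {sid!r} appears in more than one group")
        has_t0 = df.groupby("subject_id")["timepoint"].agg(lambda s: "t0" in set(s))
        if not has_t0.all():
            sid = has_t0.index[~has_t0][0]
            raise ValidationError(f"subject {sid!r} has no baseline (t0) rows")

        self.data = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    @property
    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    def groups(self) -> pd.Series:
        """Series mapping subject_id -> arm label."""
        return self.data.groupby("subject_id")["group"].first()

    def n_missing(self) -> int:
        return int(self.data["value"].isna().sum())

    def is_complete(self) -> bool:
        return self.n_missing() == 0

    def to_wide(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Pivot to one row per subject, columns ``<variable>__<timepoint>``."""
        df = self.data
        if variables is not None:
            df = df[df["variable"].isin(list(variables))]
        wide = df.pivot(
            index="subject_id", columns=["variable", "timepoint"], values="value"
        )
        wide.columns = [f"{v}__{t}" for v, t in wide.columns]
        return wide.sort_index()

    def pivot(self, variable: str) -> pd.DataFrame:
        """Subject × timepoint table for one variable."""
        df = self.data[self.data["variable"] == variable]
        return df.pivot(index="subject_id", columns="timepoint", values="value")

    @classmethod
    def from_wide(
        cls, wide: pd.DataFrame, groups: Mapping[str, str] | pd.Series
    ) -> "TrialDataset":
        """Inverse of :meth:`to_wide`; ``groups`` maps subject -> arm."""
        long = wide.stack().rename("value").reset_index()
        names = long.columns.tolist()
        long = long.rename(columns={names[0]: "subject_id", names[1]: "column"})
        parts = long["column"].str.rsplit("__", n=1, expand=True)
        long["variable"] = parts[0]
        long["timepoint"] = parts[1]
        long["group"] = long["subject_id"].map(dict(groups))
        # restore explicitly-missing cells dropped by stack()
        full = pd.MultiIndex.from_product(
            [wide.index, wide.columns], names=["subject_id", "column"]
        ).to_frame(index=False)
        parts = full["column"].str.rsplit("__", n=1, expand=True)
        full["variable"], full["timepoint"] = parts[0], parts[1]
        full["group"] = full["subject_id"].map(dict(groups))
        merged = full.merge(
            long[["subject_id", "variable", "timepoint", "value"]],
            on=["subject_id", "variable", "timepoint"],
            how="left",
        )
        return cls(merged[list(TRIAL_COLUMNS)])

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.data.copy())

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        a = self.data.sort_values(["subject_id", "timepoint", "variable"]).reset_index(drop=True)
        b = other.data.sort_values(["subject_id", "timepoint", "variable"]).reset_index(drop=True)
        return a.equals(b)


def read_trial_table(path: str | Path) -> TrialDataset:
    """Read the long-format trial outcome CSV; empty cells become missing."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return TrialDataset(df)
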