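"""Healthy Eating Index-NVS scoring: component scores, total, energy density.

The index rates a 7-day food diary against ten German (DGE) food-group
standards.  Six *adequacy* components (vegetables, fruits, grains, dairy,
fish, beverages) earn points in proportion to mean daily intake up to a
reference amount; four *moderation* components (meat, eggs, spreadable
fats, alcohol) hold full points at or below their reference and decline
linearly to zero at a configurable multiple of it.  Vegetables and fruits
are worth up to 15 points, every other component up to 10, so a diet fully
within the recommendations scores 110.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .records import (
    COMPONENTS,
    DietaryRecord,
    ValidationError,
    mean_daily_amounts,
)

logger = logging.getLogger(__name__)

ADEQUACY = "adequacy"
MODERATION = "moderation"

MAX_TOTAL = 110.0


@dataclass(frozen=True)
class ReferenceEntry:
    """Scoring standard for one component.

    ``reference_amount`` is grams/day (alcohol: grams of ethanol/day;
    beverages: grams of low-energy drinks/day, density 1 g/mL).  For
    moderation components, intake at ``zero_point_multiple x
    reference_amount`` or beyond scores zero.
    """

    component: str
    max_points: float
    reference_amount: float
    direction: str
    zero_point_multiple: float = 2.0

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValidationError(f"unknown component {self.component!r}")
        if self.max_points not in (10.0, 15.0):
            raise ValidationError(
                f"{self.component}: max_points must be 10 or 15, got {self.max_points}"
            )
        if self.reference_amount <= 0:
            raise ValidationError(f"{self.component}: reference_amount must be > 0")
        if self.direction not in (ADEQUACY, MODERATION):
            raise ValidationError(f"{self.component}: bad direction {self.direction!r}")
        if self.direction == MODERATION and self.zero_point_multiple <= 1:
            raise ValidationError(
                f"{self.component}: zero_point_multiple must exceed 1"
            )


class ReferenceTable:
    """The full 10-component standard; ships as an editable YAML file."""

    def __init__(self, entries: Iterable[ReferenceEntry]):
        entries = list(entries)
        seen = {e.component for e in entries}
        if seen != set(COMPONENTS):
            raise ValidationError(
                f"reference table must cover exactly {sorted(COMPONENTS)}, "
                f"got {sorted(seen)}"
            )
        total = sum(e.max_points for e in entries)
        if total != MAX_TOTAL:
            raise ValidationError(f"component maxima sum to {total}, expected 110")
        n15 = sum(1 for e in entries if e.max_points == 15)
        if n15 != 2:
            raise ValidationError("exactly two components may carry 15 points")
        self._entries = {e.component: e for e in entries}

    def __getitem__(self, component: str) -> ReferenceEntry:
        return self._entries[component]

    def __iter__(self):
        return (self._entries[c] for c in COMPONENTS)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "ReferenceTable":
        entries = [
            ReferenceEntry(
                component=str(item["component"]),
                max_points=float(item["max_points"]),
                reference_amount=float(item["reference_amount"]),
                direction=str(item["direction"]),
                zero_point_multiple=float(item.get("zero_point_multiple", 2.0)),
            )
            for item in raw["components"]
        ]
        return cls(entries)

    @classmethod
    def default(cls) -> "ReferenceTable":
        """The bundled DGE-based default standards."""
        text = (
            resources.files("heinvs").joinpath("data/reference_table.yaml").read_text()
        )
        return cls._from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class HeiScore:
    """Ten component scores plus their 0-110 sum."""

    subject_id: str
    timepoint: str
    component_scores: dict[str, float]
    total: float

    def as_dict(self) -> dict[str, float]:
        out = {c: self.component_scores[c] for c in COMPONENTS}
        out["hei_nvs_total"] = self.total
        return out


def score_component(intake: float, ref: ReferenceEntry) -> float:
    """Points for one component given mean daily intake (grams/day).

    Adequacy: ``max_points * min(1, intake / reference)``.
    Moderation: full points up to the reference, then a linear decline
    hitting zero at ``zero_point_multiple * reference``.  Continuous and
    piecewise-linear in intake.
    """
    if intake < 0:
        raise ValidationError(f"negative intake {intake}")
    r = ref.reference_amount
    if ref.direction == ADEQUACY:
        return ref.max_points * min(1.0, intake / r)
    zero_at = ref.zero_point_multiple * r
    if intake <= r:
        return ref.max_points
    if intake >= zero_at:
        return 0.0
    return ref.max_points * (zero_at - intake) / (zero_at - r)


def score_record(record: DietaryRecord, refs: ReferenceTable | None = None) -> HeiScore:
    """Score a diary: per-component points from mean daily amounts, total = sum."""
    refs = refs or ReferenceTable.default()
    amounts = mean_daily_amounts(record)
    scores = {c: score_component(amounts[c], refs[c]) for c in COMPONENTS}
    return HeiScore(
        subject_id=record.subject_id,
        timepoint=record.timepoint,
        component_scores=scores,
        total=sum(scores.values()),
    )


def energy_density(record: DietaryRecord, *, include_beverages: bool = False) -> float:
    """Dietary energy density in kcal/g over the whole diary.

    By convention beverages are excluded from both numerator and
    denominator; pass ``include_beverages=True`` to fold them in.
    """
    mass = 0.0
    kcal = 0.0
    for e in record.entries:
        if e.is_beverage and not include_beverages:
            continue
        mass += e.amount
        kcal += e.energy
    if mass <= 0:
        raise ValidationError(
            f"record ({record.subject_id}, {record.timepoint}) has no eligible food mass"
        )
    return kcal / mass


def energy_intake(record: DietaryRecord) -> float:
    """Mean energy intake in kcal/day (all entries, averaged over diary days)."""
    if not record.entries:
        logger.warning(
            "record (%s, %s) is empty; energy intake 0",
            record.subject_id,
            record.timepoint,
        )
        return 0.0
    return sum(e.energy for e in record.entries) / record.n_days


class HeiScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping food diaries to an index-score table.

    Parameters
    ----------
    reference_table : ReferenceTable, path, or None
        Component standards; ``None`` uses the bundled DGE defaults.
    include_beverages_in_density : bool
        Whether beverages enter the energy-density ratio.
    require_seven_days : bool
        Reject diaries that do not cover seven distinct days.
    """

    def __init__(
        self,
        reference_table: ReferenceTable | str | Path | None = None,
        include_beverages_in_density: bool = False,
        require_seven_days: bool = True,
    ):
        self.reference_table = reference_table
        self.include_beverages_in_density = include_beverages_in_density
        self.require_seven_days = require_seven_days

    def _refs(self) -> ReferenceTable:
        rt = self.reference_table
        if rt is None:
            return ReferenceTable.default()
        if isinstance(rt, (str, Path)):
            return ReferenceTable.from_yaml(rt)
        return rt

    def fit(self, X: Iterable[DietaryRecord] | None = None, y=None) -> "HeiScorer":
        self.reference_table_ = self._refs()
        return self

    def transform(self, X: Iterable[DietaryRecord]) -> pd.DataFrame:
        """Score diaries; one output row per subject x timepoint.

        Columns: the ten component scores, ``hei_nvs_total``,
        ``energy_density`` and ``energy_intake``.
        """
        if not hasattr(self, "reference_table_"):
            self.fit()
        rows = []
        for rec in X:
            if self.require_seven_days and rec.n_days != 7:
                raise ValidationError(
                    f"diary ({rec.subject_id}, {rec.timepoint}) covers "
                    f"{rec.n_days} days, not 7"
                )
            row: dict[str, object] = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "timepoint": rec.timepoint,
            }
            row.update(score_record(rec, self.reference_table_).as_dict())
            row["energy_density"] = energy_density(
                rec, include_beverages=self.include_beverages_in_density
            )
            row["energy_intake"] = energy_intake(rec)
            rows.append(row)
        return pd.DataFrame(rows)
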