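"""Component scoring rules, totals, energy density and energy intake."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heinvs import (
    COMPONENTS,
    HeiScorer,
    ReferenceEntry,
    ReferenceTable,
    ValidationError,
    energy_density,
    energy_intake,
    score_component,
    score_record,
)
from heinvs.records import DietaryRecord
from heinvs.scoring import ADEQUACY, MODERATION

from conftest import make_diary


def full_compliance_diary(refs, **kwargs):
    """Adequacy components exactly at reference, zero moderation intake."""
    amounts = {
        e.component: e.reference_amount for e in refs if e.direction == ADEQUACY
    }
    return make_diary(amounts, **kwargs)


class TestScoreComponent:
    def test_adequacy_at_reference_is_max(self, refs):
        e = refs["vegetables"]
        assert score_component(e.reference_amount, e) == e.max_points == 15

    @pytest.mark.parametrize("direction,expected", [(ADEQUACY, 0.0), (MODERATION, 10.0)])
    def test_zero_intake_boundaries(self, refs, direction, expected):
        comp = "grains" if direction == ADEQUACY else "meat"
        assert score_component(0.0, refs[comp]) == expected

    def test_proportional_adequacy(self, refs):
        # 200 g/d vegetables against the 400 g/d reference: half of 15
        assert score_component(200.0, refs["vegetables"]) == pytest.approx(7.5)

    def test_moderation_midpoint(self):
        e = ReferenceEntry("meat", 10, 100.0, MODERATION, zero_point_multiple=2.0)
        assert score_component(150.0, e) == pytest.approx(5.0)
        assert score_component(200.0, e) == 0.0
        assert score_component(500.0, e) == 0.0

    def test_negative_intake_rejected(self, refs):
        with pytest.raises(ValidationError):
            score_component(-1.0, refs["fruits"])

    @settings(max_examples=50, derandomize=True)
    @given(intake=st.floats(0, 5000), bump=st.floats(0, 100))
    def test_adequacy_monotone_moderation_declining(self, refs, intake, bump):
        adeq = refs["grains"]
        assert score_component(intake + bump, adeq) >= score_component(intake, adeq)
        mod = refs["meat"]
        above = mod.reference_amount + intake
        assert score_component(above + bump, mod) <= score_component(above, mod)


class TestScoreRecord:
    def test_full_compliance_scores_110(self, refs):
        score = score_record(full_compliance_diary(refs), refs)
        assert score.total == pytest.approx(110.0)

    def test_worst_diet_scores_0(self, refs):
        amounts = {
            e.component: e.zero_point_multiple * e.reference_amount
            for e in refs
            if e.direction == MODERATION
        }
        amounts["other"] = 500.0  # keeps the diary non-empty for every day
        assert score_record(make_diary(amounts), refs).total == 0.0

    def test_exactly_ten_component_scores(self, refs):
        score = score_record(full_compliance_diary(refs), refs)
        assert len(score.component_scores) == 10
        assert set(score.component_scores) == set(COMPONENTS)

    def test_total_independent_of_energy_content(self, refs):
        lean = full_compliance_diary(refs, energy_per_gram=0.5)
        rich = full_compliance_diary(refs, energy_per_gram=4.0)
        assert score_record(lean, refs).total == score_record(rich, refs).total == 110.0

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_caps_and_additivity_on_random_diaries(self, refs, seed):
        rng = np.random.default_rng(seed)
        amounts = {c: float(rng.uniform(0, 2000)) for c in COMPONENTS}
        score = score_record(make_diary(amounts), refs)
        for c in COMPONENTS:
            assert 0.0 <= score.component_scores[c] <= refs[c].max_points
        assert score.total == pytest.approx(sum(score.component_scores.values()))
        assert 0.0 <= score.total <= 110.0


class TestReferenceTable:
    def test_default_maxima(self, refs):
        assert refs["vegetables"].max_points == refs["fruits"].max_points == 15
        assert sum(e.max_points for e in refs) == 110

    def test_wrong_total_rejected(self, refs):
        entries = [
            ReferenceEntry(e.component, 10.0, e.reference_amount, e.direction,
                           e.zero_point_multiple)
            for e in refs
        ]
        with pytest.raises(ValidationError, match="110"):
            ReferenceTable(entries)

    def test_missing_component_rejected(self, refs):
        entries = [e for e in refs if e.component != "fish"]
        with pytest.raises(ValidationError, match="fish"):
            ReferenceTable(entries)

    def test_moderation_needs_room_to_decline(self):
        with pytest.raises(ValidationError, match="zero_point_multiple"):
            ReferenceEntry("meat", 10, 100.0, MODERATION, zero_point_multiple=1.0)


class TestEnergyDensityAndIntake:
    def test_simple_ratio(self):
        diary = make_diary({"grains": 1600.0}, energy_per_gram=1.25)
        assert energy_density(diary) == pytest.approx(1.25)

    def test_beverages_excluded_by_default(self):
        diary = make_diary({"grains": 1600.0, "beverages": 1000.0}, energy_per_gram=1.25)
        assert energy_density(diary) == pytest.approx(1.25)
        assert energy_density(diary, include_beverages=True) == pytest.approx(
            1600 * 1.25 / 2600
        )

    def test_zero_energy_diary_is_zero_density(self):
        diary = make_diary({"vegetables": 500.0}, energy_per_gram=0.0)
        assert energy_density(diary) == 0.0

    def test_no_eligible_mass_errors(self):
        diary = make_diary({"beverages": 1000.0})
        with pytest.raises(ValidationError, match="mass"):
            energy_density(diary)

    def test_energy_intake_daily_mean(self):
        diary = make_diary({"grains": 1000.0}, energy_per_gram=2.0)
        assert energy_intake(diary) == pytest.approx(2000.0)
        diary2 = make_diary({"grains": 1050.0}, energy_per_gram=2.0)
        assert energy_intake(diary2) == pytest.approx(2100.0)

    def test_empty_diary_intake_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert energy_intake(DietaryRecord("S1", "t0", [])) == 0.0
        assert "empty" in caplog.text


class TestHeiScorer:
    def test_transform_emits_score_table(self, refs):
        diary = full_compliance_diary(refs)
        table = HeiScorer().fit().transform([diary])
        assert len(table) == 1
        row = table.iloc[0]
        assert row["hei_nvs_total"] == pytest.approx(110.0)
        assert {*COMPONENTS, "energy_density", "energy_intake"} <= set(table.columns)

    def test_rejects_short_diaries(self):
        diary = make_diary({"fruits": 100.0}, n_days=5)
        with pytest.raises(ValidationError, match="5 days"):
            HeiScorer().fit().transform([diary])

    def test_sklearn_param_interface(self):
        scorer = HeiScorer()
        assert scorer.get_params()["require_seven_days"] is True
        scorer.set_params(require_seven_days=False)
        table = scorer.fit().transform([make_diary({"fruits": 100.0}, n_days=5)])
        assert len(table) == 1
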