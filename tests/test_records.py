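"""Diary and trial-table I/O, vocabulary validation, daily averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heinvs import (
    DietaryRecord,
    FoodEntry,
    TrialDataset,
    ValidationError,
    mean_daily_amounts,
    read_food_records,
    read_trial_table,
    write_food_records,
)

from conftest import make_diary


def _diary_csv(tmp_path, rows):
    path = tmp_path / "diary.csv"
    cols = "subject_id,group,timepoint,day,component,amount_g,energy_kcal,is_beverage"
    path.write_text(cols + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


class TestReadFoodRecords:
    def test_groups_entries_by_subject_timepoint(self, tmp_path):
        rows = [
            f"S1,intervention,t0,{day},{comp},100,150,False"
            for day in range(1, 8)
            for comp in ("vegetables", "fruits", "grains")
        ]
        records = read_food_records(_diary_csv(tmp_path, rows))
        assert len(records) == 1
        assert len(records[0].entries) == 21
        assert records[0].n_days == 7

    def test_empty_file_yields_empty_sequence(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            assert read_food_records(_diary_csv(tmp_path, [])) == []
        assert "no entries" in caplog.text

    def test_unknown_component_label_is_named(self, tmp_path):
        rows = ["S1,control,t0,1,candy,50,200,False"]
        with pytest.raises(ValidationError, match="candy"):
            read_food_records(_diary_csv(tmp_path, rows))

    def test_negative_amount_rejected(self, tmp_path):
        rows = ["S1,control,t0,1,fruits,-5,10,False"]
        with pytest.raises(ValidationError, match="negative"):
            read_food_records(_diary_csv(tmp_path, rows))

    def test_short_diary_rejected_by_default_but_relaxable(self, tmp_path):
        rows = [f"S1,control,t0,{d},fruits,100,50,False" for d in range(1, 4)]
        path = _diary_csv(tmp_path, rows)
        with pytest.raises(ValidationError, match="3 days"):
            read_food_records(path)
        recs = read_food_records(path, require_seven_days=False)
        assert recs[0].n_days == 3
        # averaged over the observed days, not over 7
        assert mean_daily_amounts(recs[0])["fruits"] == pytest.approx(100.0)

    def test_write_read_round_trip(self, tmp_path):
        diary = make_diary({"vegetables": 380.0, "meat": 55.0, "beverages": 1200.0})
        path = tmp_path / "out.csv"
        write_food_records([diary], path)
        (back,) = read_food_records(path)
        assert back.subject_id == diary.subject_id
        assert sorted(map(vars, back.entries), key=str) == sorted(
            map(vars, diary.entries), key=str
        )


class TestFoodEntryInvariants:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(day=0), "day"),
            (dict(day=8), "day"),
            (dict(amount=-1.0), "amount"),
            (dict(energy=-1.0), "energy"),
            (dict(component="snacks"), "component"),
            (dict(timepoint="t9"), "timepoint"),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs, match):
        base = dict(
            subject_id="S1", timepoint="t0", day=1, component="fruits",
            amount=10.0, energy=5.0,
        )
        base.update(kwargs)
        with pytest.raises(ValidationError, match=match):
            FoodEntry(**base)

    def test_entry_must_belong_to_record(self):
        e = FoodEntry("S2", "t0", 1, "fruits", 10.0, 5.0)
        with pytest.raises(ValidationError, match="belong"):
            DietaryRecord("S1", "t0", [e])


class TestMeanDailyAmounts:
    def test_constant_diary(self):
        diary = make_diary({"vegetables": 400.0})
        assert mean_daily_amounts(diary)["vegetables"] == pytest.approx(400.0)

    def test_uneven_days_average(self):
        amounts = [100, 200, 300, 0, 0, 0, 100]
        entries = [
            FoodEntry("S1", "t0", day=d + 1, component="fruits", amount=a, energy=0.0)
            for d, a in enumerate(amounts)
        ]
        rec = DietaryRecord("S1", "t0", entries)
        assert mean_daily_amounts(rec)["fruits"] == pytest.approx(700 / 7)

    def test_absent_component_is_zero(self):
        diary = make_diary({"vegetables": 400.0})
        assert mean_daily_amounts(diary)["alcohol"] == 0.0

    def test_empty_record_errors(self):
        with pytest.raises(ValidationError, match="no diary days"):
            mean_daily_amounts(DietaryRecord("S1", "t0", []))

    @settings(max_examples=25, derandomize=True)
    @given(
        amounts=st.dictionaries(
            st.sampled_from(["vegetables", "fruits", "meat"]),
            st.floats(0, 1000, allow_nan=False),
            min_size=1,
        ),
        factor=st.floats(0.1, 10, allow_nan=False),
    )
    def test_linearity_in_amounts(self, amounts, factor):
        base = mean_daily_amounts(make_diary(amounts))
        scaled = mean_daily_amounts(
            make_diary({c: a * factor for c, a in amounts.items()})
        )
        for c in base:
            assert scaled[c] == pytest.approx(base[c] * factor, abs=1e-9)


def _trial_frame(missing_t2=False):
    rows = []
    for sid, grp in (("A", "intervention"), ("B", "control")):
        for tp in ("t0", "t1", "t2", "t3"):
            for var in ("hei_nvs_total", "body_weight", "energy_density"):
                val = np.nan if (missing_t2 and tp == "t2") else 1.0
                rows.append((sid, grp, tp, var, val))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "timepoint", "variable", "value"]
    )


class TestTrialDataset:
    def test_complete_table_row_count(self, tmp_path):
        path = tmp_path / "trial.csv"
        _trial_frame().to_csv(path, index=False)
        ds = read_trial_table(path)
        assert len(ds) == 24
        assert ds.is_complete()

    def test_missing_cells_preserved(self, tmp_path):
        path = tmp_path / "trial.csv"
        _trial_frame(missing_t2=True).to_csv(path, index=False)
        ds = read_trial_table(path)
        assert ds.n_missing() == 6
        assert ds.pivot("body_weight")["t2"].isna().all()

    def test_duplicate_cell_rejected(self):
        df = _trial_frame()
        with pytest.raises(ValidationError, match="duplicate"):
            TrialDataset(pd.concat([df, df.iloc[[0]]]))

    def test_subject_in_two_groups_rejected(self):
        df = _trial_frame()
        df.loc[df.index[-1], "group"] = "intervention"
        with pytest.raises(ValidationError, match="more than one group"):
            TrialDataset(df)

    def test_subject_without_baseline_rejected(self):
        df = _trial_frame()
        df = df[~((df.subject_id == "B") & (df.timepoint == "t0"))]
        with pytest.raises(ValidationError, match="baseline"):
            TrialDataset(df)

    def test_wide_round_trip(self):
        ds = TrialDataset(_trial_frame(missing_t2=True))
        back = TrialDataset.from_wide(ds.to_wide(), ds.groups())
        assert back == ds
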