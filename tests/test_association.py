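"""Change scores, Pearson correlation, BC/BCa bootstrap intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from heinvs import (
    ImputedSet,
    bc_bootstrap_ci,
    change_scores,
    correlation_table,
    pearson_r,
    simulate_trial,
)
from heinvs.association import BCBootstrapCorrelation, _boot_correlations
from heinvs.records import TrialDataset, ValidationError

from conftest import panel_from_values


class TestChangeScores:
    def test_simple_difference(self):
        vals = np.array([[77.0, 80.0, 0, 0]])
        ds = panel_from_values({"hei_nvs_total": vals}, ["intervention"])
        delta = change_scores(ds, "t1")
        assert delta.loc["S0000", "hei_nvs_total"] == 3.0

    def test_identical_panels_give_zero(self):
        vals = np.tile(np.array([70.0]), (5, 4))
        ds = panel_from_values({"hei_nvs_total": vals}, ["control"] * 5)
        assert (change_scores(ds, "t3") == 0).all().all()

    def test_one_row_per_subject_after_imputation(self):
        import heinvs

        trial = simulate_trial(heinvs.SimConfig.default(), seed=30)
        imp = heinvs.impute(trial.dataset, m=2, seed=0)
        delta = change_scores(imp.datasets[0], "t1")
        assert len(delta) == 153
        assert delta.notna().all().all()


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),       # y = 2x + 1
            ([1, 2, 3], [-1, -2, -3], -1.0),          # y = -x
            ([1, 2, 3], [1, 3, 2], 0.5),              # hand product-moment
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_r(np.array(x, float), np.array(y, float)) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="3 pairs"):
            pearson_r(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        r = pearson_r(x, y)
        assert pearson_r(3 * x + 1, 0.5 * y - 2) == pytest.approx(r, abs=1e-12)
        assert pearson_r(-2 * x, y) == pytest.approx(-r, abs=1e-12)


class TestBCBootstrap:
    def test_exactly_linear_data_collapses_with_warning(self):
        x = np.arange(20.0)
        with pytest.warns(UserWarning, match="collapsed"):
            res = bc_bootstrap_ci(x, 2 * x + 1, B=1000, seed=0)
        assert res.r == res.ci_low == res.ci_high == 1.0

    def test_preconditions(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 30))
        with pytest.raises(ValidationError, match="B"):
            bc_bootstrap_ci(x, y, B=500, seed=0)
        with pytest.raises(ValidationError, match="10 pairs"):
            bc_bootstrap_ci(x[:5], y[:5], B=1000, seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 60))
        a = bc_bootstrap_ci(x, y, B=2000, seed=9)
        b = bc_bootstrap_ci(x, y, B=2000, seed=9)
        assert (a.ci_low, a.ci_high, a.r) == (b.ci_low, b.ci_high, b.r)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.standard_normal(153)
            y = -0.3 * x + rng.standard_normal(153)
            res = bc_bootstrap_ci(x, y, B=1000, seed=rng)
            assert res.ci_low <= res.r <= res.ci_high
            assert -1 <= res.ci_low <= res.ci_high <= 1

    def test_bc_endpoints_are_shifted_percentiles(self):
        """Recompute the BC construction from the same bootstrap draws."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal(80)
        y = 0.4 * x + rng.standard_normal(80)
        res = bc_bootstrap_ci(x, y, B=2000, seed=11)
        r_star = _boot_correlations(x, y, 2000, np.random.default_rng(11))
        z0 = ndtri(np.mean(r_star < res.r))
        lo, hi = np.quantile(r_star, ndtr(z0 + (z0 + ndtri([0.025, 0.975]))))
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    def test_bca_close_to_scipy_oracle(self):
        """Accelerated interval agrees with scipy's independent BCa."""
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        mine = bc_bootstrap_ci(x, y, B=4000, seed=12, accelerated=True)
        sci = stats.bootstrap(
            (x, y),
            lambda a, b, axis=-1: _rowwise_r(a, b),
            n_resamples=4000,
            paired=True,
            vectorized=True,
            method="BCa",
            random_state=np.random.default_rng(12),
        )
        assert mine.ci_low == pytest.approx(sci.confidence_interval.low, abs=0.03)
        assert mine.ci_high == pytest.approx(sci.confidence_interval.high, abs=0.03)

    def test_estimator_wrapper(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(60)
        y = -x + rng.standard_normal(60)
        est = BCBootstrapCorrelation(n_boot=1000, random_state=1).fit(x, y)
        assert est.ci_[0] <= est.r_ <= est.ci_[1]
        assert est.significant_


def _rowwise_r(a, b):
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = (a * b).sum(axis=-1)
    den = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
    out = num / den
    return out[0] if out.shape == (1,) else out


@pytest.fixture(scope="module")
def identical_imputations():
    rng = np.random.default_rng(7)
    n = 40
    hei = np.cumsum(rng.normal(0, 3, (n, 4)), axis=1) + 70
    dens = 1.6 - 0.02 * (hei - 70) + rng.normal(0, 0.2, (n, 4))
    ds = panel_from_values(
        {"hei_nvs_total": hei, "energy_density": dens}, ["intervention"] * n
    )
    return ImputedSet([ds.copy(), ds.copy(), ds.copy()], "none", 0)


class TestCorrelationTable:
    def test_identical_imputations_equal_single_dataset(self, identical_imputations):
        table = correlation_table(
            identical_imputations, variables=["energy_density"], B=1000, seed=13
        )
        ds = identical_imputations.datasets[0]
        for _, row in table.iterrows():
            to = row["interval"].split("-")[-1]
            delta = change_scores(ds, to)
            r = pearson_r(
                delta["hei_nvs_total"].to_numpy(), delta["energy_density"].to_numpy()
            )
            assert row["r"] == pytest.approx(r, abs=1e-9)
            assert row["ci_low"] <= row["r"] <= row["ci_high"]

    def test_table_shape_and_order(self, identical_imputations):
        table = correlation_table(
            identical_imputations, variables=["energy_density"], B=1000, seed=14
        )
        assert list(table["interval"]) == ["t0-t1", "t0-t3"]
        assert {"variable", "r", "ci_low", "ci_high", "significant"} <= set(table.columns)

    def test_stacked_mode_runs(self, identical_imputations):
        table = correlation_table(
            identical_imputations,
            variables=["energy_density"],
            B=1000,
            seed=15,
            mode="stacked",
        )
        assert len(table) == 2
        assert table["ci_low"].le(table["r"]).all()
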