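"""Boxplot summaries, bivariate splits, robust-SE regressions, balanced panel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gp_turnover import (
    balanced_panel_filter,
    bivariate_summary,
    boxplot_summary,
    fit_turnover_regression,
    format_regression_report,
    sample_practice_panel,
)
from gp_turnover.errors import EstimationError

from conftest import oracle_boxplot, oracle_sandwich_hc1


class TestBoxplotSummary:
    def test_small_odd_sample(self):
        out = boxplot_summary([1, 2, 3, 4, 5])
        row = out.iloc[0]
        assert (row["median"], row.p25, row.p75) == (3, 2, 4)
        assert (row.lower_adjacent, row.upper_adjacent) == (1, 5)
        assert row.n_outliers == 0

    def test_degenerate_constant_sample(self):
        out = boxplot_summary([7.0] * 10)
        row = out.iloc[0]
        assert row["median"] == row.p25 == row.p75 == 7.0
        assert row.lower_adjacent == row.upper_adjacent == 7.0
        assert row.outliers == []

    def test_outliers_outside_adjacent_range(self):
        out = boxplot_summary([1, 2, 3, 4, 5, 100])
        row = out.iloc[0]
        assert row.outliers == [100.0]
        assert row.upper_adjacent <= row.p75 + 1.5 * (row.p75 - row.p25)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=60))
    def test_matches_whisker_formula_oracle(self, values):
        row = boxplot_summary(values).iloc[0]
        exp = oracle_boxplot(values)
        for key in ("median", "p25", "p75", "lower_adjacent", "upper_adjacent"):
            assert row[key] == pytest.approx(exp[key], abs=1e-9)
        assert row["outliers"] == pytest.approx(exp["outliers"])
        # whisker invariants: attained data points within the fences
        assert row["p25"] <= row["median"] <= row["p75"]
        assert row["lower_adjacent"] in values and row["upper_adjacent"] in values

    def test_grouped_and_empty_groups(self):
        values = [20, 21, 22, 40, 41, 42, np.nan]
        groups = ["a", "a", "a", "b", "b", "b", "c"]
        with pytest.warns(UserWarning, match="'c'"):
            out = boxplot_summary(values, groups)
        assert out.group.tolist() == ["a", "b"]
        assert out.set_index("group").loc["a", "median"] == 21


class TestBivariateSummary:
    def test_disjoint_groups_get_their_medians(self):
        turnover = pd.DataFrame({
            "practice_id": [f"p{i}" for i in range(6)],
            "rate": [20.0] * 3 + [40.0] * 3,
        })
        profiles = pd.DataFrame({
            "practice_id": [f"p{i}" for i in range(6)],
            "ownership": ["public"] * 3 + ["private"] * 3,
        })
        out, excluded = bivariate_summary(turnover, profiles)
        assert excluded == []
        by = out[out.covariate == "ownership"].set_index("group")
        assert by.loc["public", "median"] == 20.0
        assert by.loc["private", "median"] == 40.0

    def test_unprofiled_practice_reported(self):
        turnover = pd.DataFrame({"practice_id": ["p0", "p1"], "rate": [10.0, 20.0]})
        profiles = pd.DataFrame({"practice_id": ["p0"], "ownership": ["public"]})
        out, excluded = bivariate_summary(turnover, profiles)
        assert excluded == ["p1"]
        assert out[out.covariate == "ownership"].iloc[0].n == 1


def _exact_profiles(n=24):
    rng = np.random.default_rng(5)
    return pd.DataFrame({
        "practice_id": [f"p{i:02d}" for i in range(n)],
        "size_code": rng.integers(1, 4, n),
        "workload_code": rng.integers(1, 4, n),
        "morbidity_code": rng.integers(1, 4, n),
        "deprivation_code": rng.integers(1, 4, n),
        "location": rng.choice(["city", "commuting", "town", "rural"], n),
        "ownership": rng.choice(["public", "private"], n),
    })


class TestRegression:
    def test_exact_linear_data_recovered(self):
        profiles = _exact_profiles()
        y = 12.0 + 5.0 * (profiles.deprivation_code == 3).astype(float)
        turnover = pd.DataFrame({"practice_id": profiles.practice_id, "rate": y})
        res = fit_turnover_regression(turnover, profiles, "full")
        assert res.params["const"] == pytest.approx(12.0, abs=1e-8)
        assert res.params["deprivation_3"] == pytest.approx(5.0, abs=1e-8)
        others = res.params.drop(["const", "deprivation_3"])
        assert np.allclose(others, 0.0, atol=1e-8)
        assert np.allclose(res.residuals, 0.0, atol=1e-8)

    def test_robust_se_matches_sandwich_oracle(self):
        # fixed 12-row dataset, heteroskedastic by construction
        x1 = np.array([0, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0, 1], dtype=float)
        x2 = np.array([1.2, 0.4, 2.2, 3.1, 0.5, 1.9, 2.8, 0.1, 1.1, 2.5, 0.9, 3.3])
        y = np.array([3.1, 1.2, 5.6, 9.9, 2.0, 6.3, 7.1, 0.3, 4.4, 8.2, 2.7, 11.0])
        X = np.column_stack([np.ones(12), x1, x2])
        beta_o, se_o = oracle_sandwich_hc1(X, y)
        import statsmodels.api as sm
        fit = sm.OLS(y, X).fit(cov_type="HC1")
        assert np.allclose(fit.params, beta_o, atol=1e-8)
        assert np.allclose(fit.bse, se_o, atol=1e-8)
        # and through the package interface with dummy covariates
        profiles = _exact_profiles(12)
        rng = np.random.default_rng(2)
        turnover = pd.DataFrame({
            "practice_id": profiles.practice_id,
            "rate": rng.normal(30, 8, 12),
        })
        res = fit_turnover_regression(turnover, profiles, "excl_workload")
        Xp = np.column_stack([np.ones(12)] + [
            res.model.model.exog[:, j] for j in range(1, res.model.model.exog.shape[1])
        ])
        b2, se2 = oracle_sandwich_hc1(Xp, turnover.rate.to_numpy())
        assert np.allclose(res.params.to_numpy(), b2, atol=1e-8)
        assert np.allclose(res.robust_se.to_numpy(), se2, atol=1e-8)

    def test_specifications_drop_their_columns(self):
        turnover, profiles, _ = sample_practice_panel(120, seed=3)
        full = fit_turnover_regression(turnover, profiles, "full")
        no_priv = fit_turnover_regression(turnover, profiles, "excl_private")
        no_wl = fit_turnover_regression(turnover, profiles, "excl_workload")
        assert "private" in full.params and "workload_3" in full.params
        assert "private" not in no_priv.params
        assert all(not c.startswith("workload") for c in no_wl.params.index)
        report = format_regression_report([full, no_priv, no_wl])
        assert "private" in report and "N" in report and "***" in report.splitlines()[-1]

    def test_rank_deficiency_names_columns(self):
        profiles = _exact_profiles(20)
        profiles["location"] = "city"
        profiles["ownership"] = np.where(profiles.deprivation_code == 3, "private", "public")
        profiles.loc[:, "size_code"] = profiles["deprivation_code"]  # collinear twin
        profiles["morbidity_code"] = 1
        profiles["workload_code"] = 1
        turnover = pd.DataFrame({"practice_id": profiles.practice_id,
                                 "rate": np.arange(20.0)})
        with pytest.raises(EstimationError, match="collinear"):
            fit_turnover_regression(turnover, profiles, "full")

    def test_constant_shift_moves_only_intercept(self):
        turnover, profiles, _ = sample_practice_panel(150, seed=9)
        base = fit_turnover_regression(turnover, profiles, "full")
        shifted = turnover.assign(rate=turnover.rate + 50.0)
        res = fit_turnover_regression(shifted, profiles, "full")
        assert res.params["const"] == pytest.approx(base.params["const"] + 50.0)
        pd.testing.assert_series_equal(
            res.params.drop("const"), base.params.drop("const"), atol=1e-8, rtol=0,
        )

    def test_robust_and_classical_agree_under_homoskedasticity(self):
        import statsmodels.api as sm
        turnover, profiles, _ = sample_practice_panel(4000, seed=21, noise_scale=0.0)
        rng = np.random.default_rng(33)
        turnover = turnover.assign(rate=turnover.rate + rng.normal(0, 5.0, len(turnover)))
        res = fit_turnover_regression(turnover, profiles, "full")
        classical = res.model.model.fit()  # non-robust on the same design
        ratio = res.robust_se.to_numpy() / classical.bse
        assert np.all(np.abs(ratio - 1.0) < 0.12)


class TestRegressionOnSimulatedRegistries:
    def test_zero_effects_give_null_coefficients(self):
        """With all covariate hazard effects off, no practice characteristic
        predicts turnover beyond noise."""
        from gp_turnover import SimulationConfig, run_pipeline
        cfg = SimulationConfig(n_practices=150, years=(2010, 2016), seed=61,
                               covariate_effects={}, p_open_close=(0.0, 0.0),
                               rampup_months=0)
        art = run_pipeline(config=cfg)
        res = art["regressions"]["full"]
        for name in res.params.index.drop("const"):
            assert abs(res.params[name]) <= 3.5 * res.robust_se[name], name

    def test_dropping_workload_shifts_private_toward_its_workload_load(self):
        """Private practices are leaner-staffed (higher workload); with a
        positive workload effect, omitting the workload dummies makes the
        private coefficient absorb it and move upward."""
        from gp_turnover import SimulationConfig, run_pipeline
        cfg = SimulationConfig(
            n_practices=400, years=(2010, 2016), seed=62,
            private_staff_factor=0.6,
            covariate_effects={"workload": 0.006, "private": -0.004},
            p_open_close=(0.0, 0.0), rampup_months=0,
        )
        art = run_pipeline(config=cfg)
        full = art["regressions"]["full"]
        no_wl = art["regressions"]["excl_workload"]
        assert no_wl.params["private"] > full.params["private"]


class TestBalancedPanel:
    def _annual(self, rows):
        return pd.DataFrame(rows, columns=["practice_id", "year", "rate"])

    def test_complete_panel_is_identity(self):
        annual = self._annual([(p, y, 10.0) for p in "ab" for y in (2010, 2011, 2012)])
        out = balanced_panel_filter(annual, (2010, 2012))
        assert len(out) == len(annual)

    def test_incomplete_practice_dropped(self):
        rows = [("a", y, 10.0) for y in (2010, 2011, 2012)]
        rows += [("b", y, 10.0) for y in (2010, 2012)]
        out = balanced_panel_filter(self._annual(rows), (2010, 2012))
        assert set(out.practice_id) == {"a"}

    def test_matches_direct_enumeration_on_random_panel(self, rng):
        rows = []
        for p in range(12):
            years = [y for y in range(2010, 2016) if rng.random() < 0.8]
            rows += [(f"p{p}", y, 0.0) for y in years]
        annual = self._annual(rows)
        out = balanced_panel_filter(annual, (2010, 2015))
        expected = {
            f"p{p}" for p in range(12)
            if set(annual[annual.practice_id == f"p{p}"].year) >= set(range(2010, 2016))
        }
        assert set(out.practice_id) == expected
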