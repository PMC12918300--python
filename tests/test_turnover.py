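"""Turnover rates: monthly horizons, annual/practice aggregation, imputation,
permanent-staff rates and the mixture decomposition."""

import numpy as np
import pandas as pd
import pytest

from gp_turnover import (
    HORIZONS,
    annual_turnover,
    build_spells,
    build_workforce,
    impute_missing,
    mixture_share,
    monthly_turnover,
    permanent_turnover,
    practice_average,
)
from gp_turnover.errors import (
    ConsistencyError,
    DomainError,
    ImputationError,
    ParameterError,
)

from conftest import events_from_dates, oracle_monthly_turnover, random_events


def build_both(events, data_end, min_days=1):
    roster = build_workforce(events, min_days=min_days)
    spells = build_spells(events, gap_days=365, data_end=data_end)
    return roster, spells


class TestMonthlyTurnover:
    def test_sole_member_leaving_gives_100(self):
        # member in 2015-01, last consultation inside month m+3, horizon 6
        dates = [f"2015-01-{d:02d}" for d in range(1, 11)] + ["2015-04-15"]
        data_end = pd.Timestamp("2016-12-31")
        roster, spells = build_both(events_from_dates("d", "p", dates), data_end, min_days=10)
        out = monthly_turnover(roster, spells, horizon_months=6, data_end=data_end)
        assert len(out) == 1
        assert out.iloc[0].rate == 100.0
        assert out.iloc[0].n_workforce == 1

    def test_everyone_staying_gives_0(self):
        frames = [
            events_from_dates(phys, "p", [f"{y}-{m:02d}-{d:02d}" for y in (2015, 2016, 2017)
                                          for m in range(1, 13) for d in (3, 9, 15)])
            for phys in ("a", "b")
        ]
        events = pd.concat(frames)
        data_end = pd.Timestamp("2018-12-31")
        roster, spells = build_both(events, data_end, min_days=3)
        out = monthly_turnover(roster, spells, horizon_months=12, data_end=data_end)
        # for months whose horizon ends before the (confirmed) spell ends,
        # nobody has left; later months correctly see the end-of-2017 exits
        early = out[out["month"] <= pd.Period("2015-12", "M")]
        assert len(early) == 12
        assert (early.rate == 0.0).all()
        assert (early.n_workforce == 2).all()

    def test_horizon_window_fits_inside_data(self):
        dates = ["2015-06-01", "2015-06-02"]
        data_end = pd.Timestamp("2015-12-31")
        roster, spells = build_both(events_from_dates("d", "p", dates), data_end)
        out = monthly_turnover(roster, spells, horizon_months=12, data_end=data_end)
        assert out.empty  # June 2016 > data end: month not emitted

    def test_matches_enumeration_oracle_random_panels(self, rng):
        data_end = pd.Timestamp("2016-12-31")
        for _ in range(30):
            events = random_events(rng, n_events=int(rng.integers(10, 60)),
                                   n_physicians=5, n_practices=2, span_days=2500)
            events = events[events.date <= data_end]
            if events.empty:
                continue
            roster, spells = build_both(events, data_end)
            for h in (6, 12):
                got = monthly_turnover(roster, spells, horizon_months=h, data_end=data_end)
                expected = oracle_monthly_turnover(roster, spells, h, data_end)
                assert len(got) == len(expected)
                for row in got.itertuples():
                    rate, n = expected[(row.practice_id, row.month)]
                    assert row.rate == pytest.approx(rate)
                    assert row.n_workforce == n

    def test_horizon_monotonicity(self, rng):
        data_end = pd.Timestamp("2019-12-31")
        events = random_events(rng, n_events=400, n_physicians=6, n_practices=2,
                               span_days=1800)
        roster, spells = build_both(events, data_end)
        frames = {
            h: monthly_turnover(roster, spells, horizon_months=h, data_end=data_end)
            .set_index(["practice_id", "month"])["rate"]
            for h in HORIZONS
        }
        for h1, h2 in zip(HORIZONS, HORIZONS[1:]):
            common = frames[h1].index.intersection(frames[h2].index)
            assert len(common) > 0
            assert (frames[h1][common] <= frames[h2][common] + 1e-9).all()

    def test_censor_policies(self):
        # spell ends within horizon but cannot be confirmed before data end
        dates = [f"2015-01-{d:02d}" for d in range(1, 4)] + ["2015-10-01"]
        data_end = pd.Timestamp("2016-01-31")
        roster, spells = build_both(events_from_dates("d", "p", dates), data_end, min_days=3)
        assert spells.iloc[0].censored
        ongoing = monthly_turnover(roster, spells, 12, data_end, "as_ongoing")
        ended = monthly_turnover(roster, spells, 12, data_end, "as_ended")
        excluded = monthly_turnover(roster, spells, 12, data_end, "exclude")
        assert ongoing.iloc[0].rate == 0.0
        assert ended.iloc[0].rate == 100.0
        assert excluded.empty  # sole member dropped -> no measurable month

    def test_errors(self):
        dates = ["2015-01-01"]
        data_end = pd.Timestamp("2016-12-31")
        roster, spells = build_both(events_from_dates("d", "p", dates), data_end)
        with pytest.raises(ParameterError):
            monthly_turnover(roster, spells, horizon_months=0, data_end=data_end)
        with pytest.raises(ParameterError):
            monthly_turnover(roster, spells, 12, data_end, censor_policy="nope")
        alien = spells.assign(physician_id="someone_else")
        with pytest.raises(ConsistencyError):
            monthly_turnover(roster, alien, 1, data_end)


def _monthly_frame(rows):
    df = pd.DataFrame(rows, columns=["practice_id", "month", "rate"])
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    df["horizon_months"] = 12
    df["n_workforce"] = 1
    df["defined"] = True
    return df


class TestAnnualAndPracticeAggregation:
    def test_full_year_mean(self):
        rows = [("p", f"2015-{m:02d}", 30.0) for m in range(1, 13)]
        annual = annual_turnover(_monthly_frame(rows))
        assert len(annual) == 1
        assert annual.iloc[0].rate == pytest.approx(30.0)
        assert annual.iloc[0].n_months_defined == 12

    def test_mean_over_defined_months_only(self):
        # two defined months {20, 40}: annual rate 30 regardless of the
        # ten months without a regular workforce
        rows = [("p", "2015-02", 20.0), ("p", "2015-07", 40.0)]
        annual = annual_turnover(_monthly_frame(rows))
        assert annual.iloc[0].rate == pytest.approx(30.0)
        assert annual.iloc[0].n_months_defined == 2

    def test_matches_grouped_mean_oracle(self, rng):
        rows = [
            (f"p{rng.integers(3)}", f"{rng.integers(2010, 2013)}-{rng.integers(1, 13):02d}",
             float(rng.uniform(0, 100)))
            for _ in range(200)
        ]
        monthly = _monthly_frame(rows)
        annual = annual_turnover(monthly)
        check = monthly.assign(year=monthly["month"].dt.year)
        expected = check.groupby(["practice_id", "year"])["rate"].mean()
        for row in annual.itertuples():
            assert row.rate == pytest.approx(expected[(row.practice_id, row.year)])

    def test_mixed_horizons_rejected(self):
        monthly = _monthly_frame([("p", "2015-01", 10.0), ("p", "2015-02", 10.0)])
        monthly.loc[1, "horizon_months"] = 6
        with pytest.raises(ParameterError):
            annual_turnover(monthly)

    def test_panel_pairs_emit_missing_years(self):
        monthly = _monthly_frame([("p", "2015-01", 10.0)])
        annual = annual_turnover(monthly, panel=[("p", 2015), ("p", 2016)])
        missing = annual[annual.year == 2016]
        assert missing.rate.isna().all()
        assert (missing.n_months_defined == 0).all()

    def test_imputation_uses_practice_mean(self):
        annual = annual_turnover(
            _monthly_frame([("p", "2014-01", 10.0), ("p", "2015-01", 20.0)]),
            panel=[("p", 2014), ("p", 2015), ("p", 2016)],
        )
        filled = impute_missing(annual)
        imputed = filled[filled.year == 2016]
        assert imputed.rate.iloc[0] == pytest.approx(15.0)
        assert imputed.imputed.iloc[0]
        assert filled.imputed.sum() == 1

    def test_imputation_identity_without_missing(self):
        annual = annual_turnover(_monthly_frame([("p", "2015-01", 10.0)]))
        filled = impute_missing(annual)
        pd.testing.assert_frame_equal(filled, annual)

    def test_imputation_impossible(self):
        annual = annual_turnover(_monthly_frame([("p", "2015-01", 10.0)]),
                                 panel=[("q", 2015)])
        with pytest.raises(ImputationError, match="q"):
            impute_missing(annual)

    def test_practice_average(self):
        annual = annual_turnover(
            _monthly_frame([("p", "2014-01", 20.0), ("p", "2015-01", 40.0)])
        )
        out = practice_average(annual)
        assert out.iloc[0].rate == pytest.approx(30.0)
        assert out.iloc[0].n_years == 2

    def test_aggregates_are_convex_combinations(self, rng):
        rows = [
            (f"p{rng.integers(4)}", f"{rng.integers(2010, 2014)}-{rng.integers(1, 13):02d}",
             float(rng.uniform(0, 100)))
            for _ in range(300)
        ]
        annual = annual_turnover(_monthly_frame(rows))
        assert annual.rate.between(0, 100).all()
        practice = practice_average(annual)
        assert practice.rate.between(0, 100).all()
        for row in practice.itertuples():
            rates = annual.loc[annual.practice_id == row.practice_id, "rate"]
            assert rates.min() - 1e-9 <= row.rate <= rates.max() + 1e-9


def _employment(rows):
    df = pd.DataFrame(rows, columns=["physician_id", "practice_id", "contract",
                                     "start_date", "end_date"])
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


class TestPermanentTurnover:
    def test_one_of_four_january_staff_quits(self):
        rows = [(p, "P", "permanent", "2014-05-01", None) for p in "BCD"]
        rows.append(("A", "P", "permanent", "2014-05-01", "2015-06-30"))
        out = permanent_turnover(_employment(rows), 2015)
        assert out.iloc[0].rate == pytest.approx(25.0)
        assert out.iloc[0].n_january == 4

    def test_no_quits_gives_zero(self):
        rows = [(p, "P", "permanent", "2014-05-01", None) for p in "AB"]
        out = permanent_turnover(_employment(rows), 2015)
        assert out.iloc[0].rate == 0.0

    def test_mid_year_hires_excluded(self):
        # hired in March, quits in November: in neither numerator nor denominator
        rows = [
            ("A", "P", "permanent", "2015-03-01", "2015-11-30"),
            ("B", "P", "permanent", "2014-01-01", None),
        ]
        out = permanent_turnover(_employment(rows), 2015)
        assert out.iloc[0].n_january == 1
        assert out.iloc[0].rate == 0.0

    def test_contract_filter_and_window(self):
        rows = [("A", "P", "registrar", "2014-01-01", "2015-03-31")]
        emp = _employment(rows)
        out = permanent_turnover(emp, 2015, contract="registrar")
        assert out.iloc[0].rate == 100.0
        with pytest.raises(ParameterError):
            permanent_turnover(emp, 2015)  # no permanent records
        with pytest.raises(ParameterError):
            permanent_turnover(emp, 2030, contract="registrar")


class TestMixtureShare:
    def test_printed_rates_imply_one_fifth(self):
        share = mixture_share(30.0, 14.0)
        assert share == pytest.approx((30 - 14) / (100 - 14))
        assert share == pytest.approx(0.186, abs=5e-4)

    def test_boundaries(self):
        assert mixture_share(14.0, 14.0) == 0.0
        assert mixture_share(100.0, 14.0) == 1.0

    def test_infeasible_rates(self):
        with pytest.raises(DomainError):
            mixture_share(10.0, 14.0)
        with pytest.raises(ParameterError):
            mixture_share(30.0, 90.0, temporary_exit_prob=80.0)
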