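"""Baseline proportions, death rates, standardization, and comparisons."""

import numpy as np
import pandas as pd
import pytest

from carespan.cohort import as_cohort
from carespan.rates import (baseline_month_states, baseline_proportions,
                            compare, death_rates, proportion_from_counts,
                            standard_weights, standardize)

from conftest import BASELINE, make_hazards, monthly_record, \
    single_stratum_scenario


class TestProportions:
    def test_published_style_worked_example(self):
        # 306,740 of 364,498 men without long-term care -> 84.2%
        res = proportion_from_counts(306_740, 364_498)
        assert round(100 * res["proportion"], 1) == 84.2

    def test_wald_interval_closed_form(self):
        res = proportion_from_counts(50, 100)
        assert res["lower"] == pytest.approx(0.402, abs=5e-4)
        assert res["upper"] == pytest.approx(0.598, abs=5e-4)

    def test_single_person_cohort(self):
        cohort = as_cohort([monthly_record("p", 82.0, [1] * 37)])
        table = baseline_proportions(cohort, BASELINE)
        home = table[table["state"] == "home_care"].iloc[0]
        assert home["proportion"] == 1.0
        assert home["denominator"] == 1

    def test_proportions_partition_baseline_cohort(self, small_cohort):
        table = baseline_proportions(small_cohort, BASELINE)
        sums = table.groupby(["population", "sex", "age_group"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)
        states = baseline_month_states(small_cohort, BASELINE)
        b = np.datetime64(BASELINE, "D")
        at_risk = ((small_cohort.obs_start <= b) & (small_cohort.obs_end > b)
                   & (states >= 0))
        assert table["count"].sum() == at_risk.sum()

    def test_vectorized_baseline_state_matches_record_rule(self, small_cohort):
        from carespan.records import baseline_state
        vec = baseline_month_states(small_cohort, BASELINE)
        records = small_cohort.to_records()
        for i in range(0, len(records), 17):
            expected = baseline_state(records[i], BASELINE)
            got = None if vec[i] < 0 else int(vec[i])
            assert got == expected


def _death_rate_cohort():
    """400 persons, same stratum: 100 die at one year, 300 survive 3 years."""
    records = []
    for i in range(300):
        records.append(monthly_record(f"s{i}", 77.0, [0] * 37))
    for i in range(100):
        records.append(monthly_record(
            f"d{i}", 77.0, [0] * 13, end_reason="death",
            end_offset_days=31 + round(365.25)))
    return as_cohort(records)


class TestDeathRates:
    def test_rate_and_poisson_interval(self):
        table = death_rates(_death_rate_cohort(), BASELINE, 3.0)
        row = table.iloc[0]
        assert row["deaths"] == 100
        assert row["person_years"] == pytest.approx(1000.0, rel=1e-3)
        assert row["rate"] == pytest.approx(100.0, rel=1e-3)
        # rate +/- 1.96 * 1000 * sqrt(D) / PY
        assert row["lower"] == pytest.approx(80.4, abs=0.2)
        assert row["upper"] == pytest.approx(119.6, abs=0.2)

    def test_zero_deaths_flagged_low_information(self):
        records = [monthly_record(f"p{i}", 76.0, [0] * 37) for i in range(20)]
        table = death_rates(as_cohort(records), BASELINE, 3.0)
        row = table.iloc[0]
        assert row["rate"] == 0.0
        assert (row["lower"], row["upper"]) == (0.0, 0.0)
        assert bool(row["low_information"])

    def test_constant_hazard_recovered(self):
        # per-interval death probability equivalent to 0.05 / person-year
        q = 1.0 - np.exp(-0.05 / 4)
        sc = single_stratum_scenario(make_hazards(death=(q, q, q)), n=10_000,
                                     seed=4)
        from carespan.simulate import simulate_cohort
        table = death_rates(simulate_cohort(sc), BASELINE, 3.0)
        deaths = table["deaths"].sum()
        py = table["person_years"].sum()
        rate = 1000 * deaths / py
        se = 1000 * np.sqrt(deaths) / py
        assert rate == pytest.approx(50.0, abs=3 * se)

    def test_additive_under_concatenation(self, small_cohort):
        full = death_rates(small_cohort, BASELINE, 3.0)
        n = len(small_cohort)
        half_a = death_rates(small_cohort.subset(np.arange(n // 2)),
                             BASELINE, 3.0)
        half_b = death_rates(small_cohort.subset(np.arange(n // 2, n)),
                             BASELINE, 3.0)
        key = ["population", "sex", "age_group", "state"]
        merged = (pd.concat([half_a, half_b])
                  .groupby(key, as_index=False)[["deaths", "person_years"]]
                  .sum())
        joined = full.merge(merged, on=key, suffixes=("", "_sum"))
        assert (joined["deaths"] == joined["deaths_sum"]).all()
        assert np.allclose(joined["person_years"], joined["person_years_sum"])

    def test_follow_up_length_caps_exposure(self):
        cohort = _death_rate_cohort()
        five = death_rates(cohort, BASELINE, 5.0)
        # observation ends ~3 calendar years after baseline, so widening the
        # window changes exposure only by the calendar-vs-365.25 rounding
        assert five["person_years"].sum() == pytest.approx(
            death_rates(cohort, BASELINE, 3.0)["person_years"].sum(), rel=1e-3)


class TestStandardize:
    def _table(self, rates, sex="female", pop="A"):
        groups = [f"g{i}" for i in range(len(rates))]
        return pd.DataFrame({
            "population": pop, "sex": sex, "age_group": groups,
            "state": "no_care", "rate": rates,
            "var": [1.0] * len(rates),
        })

    def _weights(self, w, sex="female"):
        return pd.DataFrame({"sex": sex, "age_group": [f"g{i}" for i in range(len(w))],
                             "weight": w})

    def test_equal_weights_average(self):
        out = standardize(self._table([10.0, 20.0]), self._weights([0.5, 0.5]))
        assert out["rate"].iloc[0] == pytest.approx(15.0)

    def test_concentrated_weights_select_group(self):
        out = standardize(self._table([10.0, 20.0]), self._weights([1.0, 0.0]))
        assert out["rate"].iloc[0] == pytest.approx(10.0)

    def test_missing_weight_is_hard_error(self):
        with pytest.raises(ValueError, match="g1"):
            standardize(self._table([10.0, 20.0]), self._weights([1.0])[:1])

    def test_own_weights_return_crude_proportion(self, small_cohort):
        """Standardizing with a population's own age structure is the identity."""
        props = baseline_proportions(small_cohort, BASELINE)
        one = props[(props["population"] == "A") & (props["sex"] == "female")]
        weights = standard_weights(one, by=("sex",))
        std = standardize(one, weights, value="proportion")
        crude = (one.groupby("state")["count"].sum()
                 / one["count"].sum())
        for _, row in std.iterrows():
            assert row["proportion"] == pytest.approx(crude[row["state"]],
                                                      abs=1e-12)

    def test_standard_weights_sum_to_one(self, small_cohort):
        props = baseline_proportions(small_cohort, BASELINE)
        for by in [("sex",), ("sex", "state")]:
            w = standard_weights(props, by=by)
            sums = w.groupby(list(by))["weight"].sum()
            assert np.allclose(sums, 1.0, atol=1e-12)


class TestCompare:
    def _row(self, rate, deaths, py, pop):
        return pd.DataFrame({
            "population": [pop], "sex": ["male"], "age_group": ["75-79"],
            "state": ["no_care"], "rate": [rate],
            "var": [(1000**2) * deaths / py**2],
        })

    def test_identical_tables_give_null_comparison(self):
        a = self._row(100.0, 100, 1000.0, "A")
        diff = compare(a, a.assign(population="B"), mode="difference")
        ratio = compare(a, a.assign(population="B"), mode="ratio")
        assert diff["difference"].iloc[0] == 0.0
        assert ratio["ratio"].iloc[0] == 1.0

    def test_difference_and_ratio_values(self):
        a = self._row(100.0, 100, 1000.0, "A")
        b = self._row(50.0, 50, 1000.0, "B")
        diff = compare(a, b, mode="difference")
        assert diff["difference"].iloc[0] == pytest.approx(50.0)
        expected_half_width = 1.96 * 1000 * np.sqrt(100 + 50) / 1000
        assert diff["upper"].iloc[0] - diff["difference"].iloc[0] == \
            pytest.approx(expected_half_width, rel=1e-9)
        assert diff["comparison"].iloc[0] == "A-B"
        ratio = compare(a, b, mode="ratio")
        assert ratio["ratio"].iloc[0] == pytest.approx(2.0)

    def test_zero_denominator_ratio_flagged(self):
        a = self._row(100.0, 100, 1000.0, "A")
        b = self._row(0.0, 0, 1000.0, "B")
        out = compare(a, b, mode="ratio")
        assert np.isnan(out["ratio"].iloc[0])
        assert bool(out["undefined"].iloc[0])
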