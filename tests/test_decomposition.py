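"""Exact additivity and symmetry of the rate-difference decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carespan.decomposition import (decompose, decompose_standardized,
                                    decompose_table)

STATES = ["no_care", "home_care", "care_home"]


def tables(pi, m, pop="A", sex="female", age_group="75-79"):
    """Proportion and rate tables for one stratum from share/rate vectors."""
    props = pd.DataFrame({
        "population": pop, "sex": sex, "age_group": age_group,
        "state": STATES, "proportion": pi, "var": 0.0,
    })
    rates = pd.DataFrame({
        "population": pop, "sex": sex, "age_group": age_group,
        "state": STATES, "rate": m, "var": 0.0,
    })
    return props, rates


def random_inputs(rng):
    pi_a = rng.dirichlet([3, 2, 1])
    pi_b = rng.dirichlet([3, 2, 1])
    m_a = rng.uniform(5, 400, size=3)
    m_b = rng.uniform(5, 400, size=3)
    return pi_a, m_a, pi_b, m_b


def run(pi_a, m_a, pi_b, m_b, method="kitagawa"):
    pa, ra = tables(pi_a, m_a, "A")
    pb, rb = tables(pi_b, m_b, "B")
    return decompose(ra, rb, pa, pb, "75-79", "female", method=method)


class TestDecompose:
    def test_identical_populations_give_zero(self):
        pi = np.array([0.8, 0.15, 0.05])
        m = np.array([20.0, 80.0, 250.0])
        row = run(pi, m, pi, m)
        assert row.total_difference == 0.0
        assert row.composition == 0.0
        assert all(v == 0.0 for v in row.rate_components.values())

    def test_two_state_toy_example(self):
        # A: rates (10, 100), shares (0.9, 0.1); B: (12, 140), (0.8, 0.2);
        # total difference 19.0 - 37.6 = -18.6 per 1000 PY, split exactly
        row = run(np.array([0.9, 0.1, 0.0]), np.array([10.0, 100.0, 0.0]),
                  np.array([0.8, 0.2, 0.0]), np.array([12.0, 140.0, 0.0]))
        assert row.total_difference == pytest.approx(-18.6, abs=1e-12)
        parts = row.composition + sum(row.rate_components.values())
        assert parts == pytest.approx(-18.6, abs=1e-12)

    def test_equal_rates_put_everything_in_composition(self):
        m = np.array([15.0, 90.0, 300.0])
        row = run(np.array([0.7, 0.2, 0.1]), m, np.array([0.5, 0.3, 0.2]), m)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in row.rate_components.values())
        assert row.composition == pytest.approx(row.total_difference, abs=1e-12)

    def test_additivity_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            row = run(*random_inputs(rng))
            parts = row.composition + sum(row.rate_components.values())
            assert abs(parts - row.total_difference) < 1e-9

    def test_antisymmetry_under_population_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pi_a, m_a, pi_b, m_b = random_inputs(rng)
            fwd = run(pi_a, m_a, pi_b, m_b)
            rev = run(pi_b, m_b, pi_a, m_a)
            assert rev.total_difference == pytest.approx(-fwd.total_difference,
                                                         abs=1e-12)
            assert rev.composition == pytest.approx(-fwd.composition, abs=1e-12)
            for s in STATES:
                assert rev.rate_components[s] == pytest.approx(
                    -fwd.rate_components[s], abs=1e-12)

    def test_kitagawa_is_mean_of_stepwise_orders(self):
        """The averaged decomposition equals the mean of the two pure
        replacement orders — an algebraic identity checked numerically."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            args = random_inputs(rng)
            kit = run(*args, method="kitagawa")
            ab = run(*args, method="stepwise_ab")
            ba = run(*args, method="stepwise_ba")
            assert kit.composition == pytest.approx(
                0.5 * (ab.composition + ba.composition), abs=1e-9)
            for s in STATES:
                assert kit.rate_components[s] == pytest.approx(
                    0.5 * (ab.rate_components[s] + ba.rate_components[s]),
                    abs=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
           st.lists(st.floats(0.0, 500.0), min_size=6, max_size=6))
    def test_additivity_and_antisymmetry_hold_for_any_inputs(self, raw_pi, m):
        """Exact additivity and swap-antisymmetry over arbitrary shares/rates."""
        pi_a = np.array(raw_pi[:3]) / sum(raw_pi[:3])
        pi_b = np.array(raw_pi[3:]) / sum(raw_pi[3:])
        m_a, m_b = np.array(m[:3]), np.array(m[3:])
        row = run(pi_a, m_a, pi_b, m_b)
        parts = row.composition + sum(row.rate_components.values())
        assert abs(parts - row.total_difference) < 1e-9
        rev = run(pi_b, m_b, pi_a, m_a)
        assert abs(rev.total_difference + row.total_difference) < 1e-9

    def test_invalid_shares_rejected(self):
        pa, ra = tables([0.5, 0.2, 0.1], [10, 20, 30], "A")
        pb, rb = tables([0.8, 0.15, 0.05], [10, 20, 30], "B")
        with pytest.raises(ValueError, match="sum"):
            decompose(ra, rb, pa, pb, "75-79", "female")

    def test_missing_state_cell_named(self):
        pa, ra = tables([0.8, 0.15, 0.05], [10, 20, 30], "A")
        pb, rb = tables([0.8, 0.15, 0.05], [10, 20, 30], "B")
        with pytest.raises(ValueError, match="care_home"):
            decompose(ra[ra["state"] != "care_home"], rb, pa, pb,
                      "75-79", "female")


class TestStandardized:
    def _multi_group(self, rng, groups):
        frames_p, frames_r = [], []
        truth = {}
        for g in groups:
            pi_a, m_a, pi_b, m_b = random_inputs(rng)
            pa, ra = tables(pi_a, m_a, "A", age_group=g)
            pb, rb = tables(pi_b, m_b, "B", age_group=g)
            frames_p += [pa, pb]
            frames_r += [ra, rb]
            truth[g] = (pi_a, m_a, pi_b, m_b)
        return (pd.concat(frames_p, ignore_index=True),
                pd.concat(frames_r, ignore_index=True), truth)

    def test_single_group_equals_unstandardized(self):
        rng = np.random.default_rng(3)
        pi_a, m_a, pi_b, m_b = random_inputs(rng)
        pa, ra = tables(pi_a, m_a, "A")
        pb, rb = tables(pi_b, m_b, "B")
        w = pd.DataFrame({"sex": ["female"], "age_group": ["75-79"],
                          "weight": [1.0]})
        std = decompose_standardized(ra, rb, pa, pb, w, "female")
        plain = decompose(ra, rb, pa, pb, "75-79", "female")
        assert std.total_difference == pytest.approx(plain.total_difference)
        assert std.composition == pytest.approx(plain.composition)

    def test_linearity_in_age_specific_components(self):
        rng = np.random.default_rng(4)
        groups = ["75-79", "80-84", "85-89"]
        props, rates, _ = self._multi_group(rng, groups)
        w_vals = rng.dirichlet([1, 1, 1])
        weights = pd.DataFrame({"sex": "female", "age_group": groups,
                                "weight": w_vals})
        pa = props[props["population"] == "A"]
        pb = props[props["population"] == "B"]
        ra = rates[rates["population"] == "A"]
        rb = rates[rates["population"] == "B"]
        std = decompose_standardized(ra, rb, pa, pb, weights, "female")
        manual_total = sum(
            w * decompose(ra, rb, pa, pb, g, "female").total_difference
            for g, w in zip(groups, w_vals))
        assert std.total_difference == pytest.approx(manual_total, abs=1e-9)
        parts = std.composition + sum(std.rate_components.values())
        assert parts == pytest.approx(std.total_difference, abs=1e-9)

    def test_table_includes_standardized_row(self, small_cohort):
        from carespan.rates import (baseline_proportions, death_rates,
                                    standard_weights)
        from conftest import BASELINE
        props = baseline_proportions(small_cohort, BASELINE)
        rates = death_rates(small_cohort, BASELINE, 3.0)
        weights = standard_weights(props, by=("sex",))
        table = decompose_table(rates, props, "B", "A", weights=weights)
        assert (table["age_group"] == "standardized").sum() == 2  # both sexes
        resid = (table["total_difference"] - table["composition"]
                 - table[[f"rate_{s}" for s in STATES]].sum(axis=1))
        assert np.abs(resid).max() < 1e-9
        assert set(table["comparison"]) == {"B-A"}
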