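"""Transition counting, raw probabilities, and P-spline surface smoothing."""

import numpy as np
import pytest

from carespan.cohort import as_cohort
from carespan.estimation import (SplineConfig, TransitionCounts,
                                 count_transitions, default_grid,
                                 raw_probabilities, smooth_probabilities)
from carespan.simulate import true_transition_surface
from carespan.states import State

from conftest import monthly_record


def _home_care_cohort_at_80():
    """10 persons in home care at age 80.0; by 80.25: 2 recover to no care,
    1 moves to a care home, 1 dies, 6 remain."""
    records = []
    # baseline age 79.95: age 80.0 falls in month 1, age 80.25 in month 4
    for i in range(2):
        records.append(monthly_record(f"r{i}", 79.95, [1, 1, 1, 1, 0, 0]))
    for i in range(6):
        records.append(monthly_record(f"s{i}", 79.95, [1] * 6))
    records.append(monthly_record("c0", 79.95, [1, 1, 1, 1, 2, 2]))
    records.append(monthly_record("d0", 79.95, [1, 1, 1], end_reason="death",
                                  end_offset_days=100))
    return as_cohort(records)


class TestCountTransitions:
    def test_worked_home_care_interval(self):
        counts = count_transitions(_home_care_cohort_at_80())
        k = np.flatnonzero(np.abs(counts.ages - 80.0) < 1e-9)[0]
        row = counts.counts[k, int(State.HOME_CARE), :]
        assert row.tolist() == [2, 6, 1, 1]
        assert counts.at_risk[k, int(State.HOME_CARE)] == 10

    def test_cohort_without_events_stays_diagonal(self):
        records = [monthly_record(f"p{i}", 76.0 + i / 7, [0] * 37)
                   for i in range(10)]
        counts = count_transitions(as_cohort(records))
        off_diag = counts.counts.sum() - counts.counts[:, 0, 0].sum()
        assert off_diag == 0
        assert counts.counts[:, 0, 0].sum() > 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            count_transitions(_home_care_cohort_at_80(), grid=np.array([]))

    def test_counts_match_generator_oracle(self, recovery_scenario,
                                           recovery_cohort):
        """Raw frequencies track the exact surface within 3 binomial SEs.

        With ~800 compared cells per stratum, a ~0.3% violation fraction is
        expected at the 3-SE level by chance alone; we allow up to 1%.
        """
        from carespan.records import follow_up_end
        from conftest import BASELINE
        window = follow_up_end(BASELINE, 3.0)
        checked = violations = 0
        for pop, sex in [("A", "female"), ("B", "male")]:
            sub = recovery_cohort.filter(population=pop, sex=sex)
            counts = count_transitions(sub, window_end=window)
            truth = true_transition_surface(recovery_scenario, pop, sex)
            raw = raw_probabilities(counts)
            for i in range(3):
                n = counts.at_risk[:, i]
                ok = n >= 25
                for j in range(4):
                    if j == i:
                        continue
                    p = truth.matrices[ok, i, j]
                    se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n[ok])
                    err = np.abs(raw.matrices[ok, i, j] - p)
                    checked += ok.sum()
                    violations += (err > 3 * se).sum()
        assert checked > 1000
        assert violations / checked < 0.01


class TestRawProbabilities:
    def test_simple_division(self):
        raw = raw_probabilities(count_transitions(_home_care_cohort_at_80()))
        k = raw.index_of(80.0)
        assert raw.matrices[k, 1, :].tolist() == [0.2, 0.6, 0.1, 0.1]

    def test_zero_at_risk_rows_flagged_missing(self):
        counts = count_transitions(_home_care_cohort_at_80())
        raw = raw_probabilities(counts)
        k = raw.index_of(80.0)
        assert raw.missing[k, int(State.CARE_HOME)]      # nobody there yet
        assert not raw.missing[k, int(State.HOME_CARE)]

    def test_doubled_cohort_leaves_probabilities_unchanged(self):
        cohort = _home_care_cohort_at_80()
        single = count_transitions(cohort)
        idx = np.concatenate([np.arange(len(cohort))] * 2)
        double = count_transitions(cohort.subset(idx))
        assert np.array_equal(double.counts, 2 * single.counts)
        ok = single.at_risk > 0
        p1 = raw_probabilities(single).matrices
        p2 = raw_probabilities(double).matrices
        assert np.allclose(p1[:, :3][ok[:, :3]], p2[:, :3][ok[:, :3]])


def _synthetic_counts(p_exit: float, n_per_age: int = 5000,
                      seed: int = 0) -> TransitionCounts:
    """Counts with an age-constant no-care -> home-care probability."""
    rng = np.random.default_rng(seed)
    grid = default_grid()
    k = len(grid)
    counts = np.zeros((k, 4, 4), dtype=np.int64)
    events = rng.binomial(n_per_age, p_exit, size=k)
    counts[:, 0, 1] = events
    counts[:, 0, 0] = n_per_age - events
    counts[:, 1, 1] = 200
    counts[:, 2, 2] = 200
    return TransitionCounts(ages=grid, delta=0.25, counts=counts,
                            at_risk=counts.sum(axis=2))


class TestSmoothing:
    def test_constant_probability_recovered(self):
        surface = smooth_probabilities(_synthetic_counts(0.1))
        assert np.abs(surface.matrices[:, 0, 1] - 0.1).max() < 0.01

    def test_rows_sum_to_one_and_dead_is_absorbing(self, recovery_cohort):
        counts = count_transitions(
            recovery_cohort.filter(population="A", sex="male"))
        surface = smooth_probabilities(counts)
        assert np.abs(surface.matrices.sum(axis=2) - 1).max() < 1e-9
        assert np.allclose(surface.matrices[:, 3, :], [0, 0, 0, 1])
        assert (surface.matrices[:, 3, :3] == 0).all()

    def test_smooth_surface_reproduced_within_two_se(self):
        """Data generated from a logit-smooth surface is recovered pointwise."""
        rng = np.random.default_rng(8)
        grid = default_grid()
        p = 1 / (1 + np.exp(-(-6 + 0.09 * (grid - 70))))
        n = 10_000
        counts = np.zeros((len(grid), 4, 4), dtype=np.int64)
        counts[:, 0, 3] = rng.binomial(n, p)
        counts[:, 0, 0] = n - counts[:, 0, 3]
        counts[:, 1, 1] = 200
        counts[:, 2, 2] = 200
        tc = TransitionCounts(ages=grid, delta=0.25, counts=counts,
                              at_risk=counts.sum(axis=2))
        fit = smooth_probabilities(tc).matrices[:, 0, 3]
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(fit - p) <= 2 * se).all()

    def test_too_few_ages_for_basis_suggests_reduction(self):
        counts = count_transitions(_home_care_cohort_at_80())
        with pytest.raises(ValueError, match="n_basis"):
            smooth_probabilities(counts)

    def test_reduced_basis_handles_sparse_data(self):
        counts = _synthetic_counts(0.05)
        cfg = SplineConfig(n_basis=6)
        surface = smooth_probabilities(counts, cfg)
        assert np.abs(surface.matrices[:, 0, 1] - 0.05).max() < 0.01


class TestSurfaceSerialization:
    def test_csv_round_trip(self, tmp_path):
        counts = count_transitions(_home_care_cohort_at_80())
        raw = raw_probabilities(counts)
        path = tmp_path / "surface.csv"
        raw.to_csv(path)
        from carespan.estimation import TransitionSurface
        back = TransitionSurface.from_csv(path)
        assert np.allclose(back.matrices, raw.matrices, atol=1e-12)
        assert np.array_equal(back.missing, raw.missing)
        assert back.kind == "raw"
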