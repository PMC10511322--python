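import numpy as np
import pandas as pd
import pytest

from smokeatlas import (DailyField, GridSpec, PopulationRaster, SfapThresholds,
                        adjust_to_reference, aggregate_population,
                        days_per_person, flag_sfap, people_exposed,
                        person_days, pop_weighted_mean, summarize_exposure)
from smokeatlas.exposure import CATEGORIES, SfapFlags


def _field(grid, vals, start="2018-01-01"):
    vals = np.asarray(vals, dtype=float)
    dates = pd.date_range(start, periods=vals.shape[0])
    return DailyField(grid, dates, vals)


def _two_cell_setup():
    """The worked example: populations {100, 50}; cell 1 flagged on day 1,
    both cells on day 2 -> 250 person-days."""
    grid = GridSpec(0.0, 0.0, 1.0, 1.0, 1, 2)
    pm_total = _field(grid, [[[20.0, 10.0]], [[30.0, 25.0]]])
    pm_fire = _field(grid, [[[15.0, 1.0]], [[20.0, 20.0]]])
    o3_total = _field(grid, np.zeros((2, 1, 2)))
    o3_fire = _field(grid, np.zeros((2, 1, 2)))
    pop = PopulationRaster(grid, 2018, np.array([[100.0, 50.0]]),
                           np.zeros((1, 2), dtype=int), {0: 150.0})
    return pm_total, pm_fire, o3_total, o3_fire, pop


class TestAggregatePopulation:
    def test_four_fine_cells_sum(self):
        fine = GridSpec(0.25, 0.25, 0.5, 0.5, 2, 2)
        target = GridSpec(0.5, 0.5, 1.0, 1.0, 1, 1)
        out = aggregate_population(np.full((2, 2), 10.0), fine, target)
        assert out[0, 0] == 40.0

    def test_total_conserved(self, rng):
        fine = GridSpec(0.125, 0.125, 0.25, 0.25, 8, 12)
        target = GridSpec(0.5, 0.5, 1.0, 1.0, 2, 3)
        counts = rng.uniform(0, 100, (8, 12))
        out = aggregate_population(counts, fine, target)
        assert out.sum() == pytest.approx(counts.sum(), rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        fine = GridSpec(0.125, 0.125, 0.25, 0.25, 4, 8)
        target = GridSpec(0.25, 0.5, 0.5, 1.0, 2, 2)
        counts = rng.uniform(0, 50, (4, 8))
        out = aggregate_population(counts, fine, target)
        for i in range(2):
            for j in range(2):
                expect = counts[2 * i:2 * i + 2, 4 * j:4 * j + 4].sum()
                assert out[i, j] == pytest.approx(expect, rel=1e-12)

    def test_non_nesting_rejected(self):
        fine = GridSpec(0.0, 0.0, 0.3, 0.3, 4, 4)
        target = GridSpec(0.0, 0.0, 1.0, 1.0, 2, 2)
        with pytest.raises(ValueError):
            aggregate_population(np.ones((4, 4)), fine, target)


class TestAdjustToReference:
    def _raster(self, counts, country, refs):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, *np.asarray(counts).shape)
        return PopulationRaster(grid, 2018, counts, country, refs)

    def test_coefficient_is_ratio(self):
        pop = self._raster(np.full((2, 2), 200.0), np.zeros((2, 2), int),
                           {0: 1000.0})
        out = adjust_to_reference(pop)
        np.testing.assert_allclose(out.counts, 250.0)  # 800 -> 1000, x1.25

    def test_identity_when_reference_matches(self):
        pop = self._raster(np.full((2, 2), 250.0), np.zeros((2, 2), int),
                           {0: 1000.0})
        out = adjust_to_reference(pop)
        np.testing.assert_allclose(out.counts, pop.counts)

    def test_two_countries_distinct_coefficients(self):
        country = np.array([[0, 0], [1, 1]])
        pop = self._raster(np.array([[100.0, 300.0], [50.0, 150.0]]), country,
                           {0: 800.0, 1: 100.0})
        out = adjust_to_reference(pop)
        sums = out.country_sums()
        assert sums[0] == pytest.approx(800.0, rel=1e-6)
        assert sums[1] == pytest.approx(100.0, rel=1e-6)

    def test_idempotent(self, tiny_world):
        once = adjust_to_reference(tiny_world.population[0])
        twice = adjust_to_reference(once)
        np.testing.assert_allclose(twice.counts, once.counts, rtol=1e-12)

    def test_zero_raster_sum_with_positive_reference(self):
        country = np.array([[0, 0], [1, 1]])
        counts = np.array([[10.0, 10.0], [0.0, 0.0]])
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 2, 2)
        pop = PopulationRaster(grid, 2018, counts, country, {0: 50.0, 1: 5.0})
        with pytest.raises(ValueError):
            adjust_to_reference(pop)


class TestFlagSfap:
    @pytest.mark.parametrize("pm,pmf,o3,o3f,expect", [
        (20.0, 12.0, 50.0, 0.0, "pm_only"),    # 12/20 = 0.6 >= 0.5
        (20.0, 5.0, 50.0, 0.0, "none"),        # fraction 0.25
        (20.0, 12.0, 120.0, 70.0, "both"),
        (10.0, 9.0, 120.0, 70.0, "o3_only"),   # PM below guideline
        (15.0, 10.0, 100.0, 60.0, "none"),     # exactly at guideline: strict
        (20.0, 10.0, 50.0, 0.0, "pm_only"),    # share exactly 0.5: inclusive
        (20.0, -12.0, 50.0, 0.0, "none"),      # negative fire never qualifies
    ])
    def test_joint_criteria(self, pm, pmf, o3, o3f, expect):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 1, 1)
        flags = flag_sfap(_field(grid, [[[pm]]]), _field(grid, [[[pmf]]]),
                          _field(grid, [[[o3]]]),
                          DailyField(grid, pd.date_range("2018-01-01", periods=1),
                                     np.array([[[o3f]]])))
        assert CATEGORIES[flags.category[0, 0, 0]] == expect

    def test_nan_counts_as_missing_not_flagged(self):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 1, 1)
        flags = flag_sfap(_field(grid, [[[np.nan]]]), _field(grid, [[[10.0]]]),
                          _field(grid, [[[50.0]]]), _field(grid, [[[0.0]]]))
        assert flags.category[0, 0, 0] == 0
        assert flags.n_missing == 1

    def test_flag_iff_category(self, tiny_world):
        w = tiny_world
        flags = flag_sfap(w.truth_total["pm25"], w.truth_fire["pm25"],
                          w.truth_total["o3"], w.truth_fire["o3"])
        np.testing.assert_array_equal(flags.flag, flags.category != 0)


class TestMetrics:
    def test_worked_example_250_person_days(self):
        pm_total, pm_fire, o3_total, o3_fire, pop = _two_cell_setup()
        flags = flag_sfap(pm_total, pm_fire, o3_total, o3_fire)
        assert person_days(flags, pop) == 250.0
        assert people_exposed(flags, pop) == 150.0
        assert days_per_person(250.0, pop) == pytest.approx(250.0 / 150.0)

    def test_no_flags_zero(self):
        pm_total, pm_fire, o3_total, o3_fire, pop = _two_cell_setup()
        flags = flag_sfap(pm_total, pm_fire, o3_total, o3_fire,
                          SfapThresholds(pm_guideline=1e9))
        assert person_days(flags, pop) == 0.0
        assert people_exposed(flags, pop) == 0.0

    def test_person_days_triple_loop_oracle(self, rng):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 3, 4)
        cat = rng.integers(0, 4, size=(6, 3, 4)).astype(np.int8)
        flags = SfapFlags(grid, pd.date_range("2018-01-01", periods=6), cat,
                          SfapThresholds())
        counts = rng.integers(0, 1000, (3, 4)).astype(float)
        pop = PopulationRaster(grid, 2018, counts, np.zeros((3, 4), int),
                               {0: counts.sum()})
        expect = 0.0
        for t in range(6):
            for i in range(3):
                for j in range(4):
                    if cat[t, i, j] != 0:
                        expect += counts[i, j]
        assert person_days(flags, pop) == expect

    def test_people_exposed_never_exceeds_population(self, rng):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 3, 4)
        for _ in range(10):
            cat = (rng.uniform(size=(6, 3, 4)) < 0.1).astype(np.int8)
            flags = SfapFlags(grid, pd.date_range("2018-01-01", periods=6),
                              cat, SfapThresholds())
            counts = rng.integers(0, 100, (3, 4)).astype(float)
            pop = PopulationRaster(grid, 2018, counts, np.zeros((3, 4), int),
                                   {0: max(counts.sum(), 1.0)})
            assert people_exposed(flags, pop) <= pop.total

    def test_bookkeeping_identity(self, rng):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 3, 4)
        cat = rng.integers(0, 4, size=(6, 3, 4)).astype(np.int8)
        flags = SfapFlags(grid, pd.date_range("2018-01-01", periods=6), cat,
                          SfapThresholds())
        counts = rng.integers(1, 1000, (3, 4)).astype(float)
        pop = PopulationRaster(grid, 2018, counts, np.zeros((3, 4), int),
                               {0: counts.sum()})
        pdays = person_days(flags, pop)
        assert abs(pdays - days_per_person(pdays, pop) * pop.total) < 1e-9

    def test_category_partition_exact(self, rng):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 3, 4)
        cat = rng.integers(0, 4, size=(6, 3, 4)).astype(np.int8)
        flags = SfapFlags(grid, pd.date_range("2018-01-01", periods=6), cat,
                          SfapThresholds())
        counts = rng.integers(0, 1000, (3, 4)).astype(float)
        pop = PopulationRaster(grid, 2018, counts, np.zeros((3, 4), int),
                               {0: max(counts.sum(), 1.0)})
        total = person_days(flags, pop)
        parts = sum(person_days(flags, pop, c) for c in CATEGORIES[1:])
        assert total == parts

    def test_threshold_monotonicity(self, tiny_world):
        w = tiny_world
        pop = w.population[0]
        args = (w.truth_total["pm25"], w.truth_fire["pm25"],
                w.truth_total["o3"], w.truth_fire["o3"])
        loose = flag_sfap(*args, SfapThresholds(pm_guideline=10.0))
        strict = flag_sfap(*args, SfapThresholds(pm_guideline=15.0))
        assert person_days(loose, pop) >= person_days(strict, pop)


class TestPopWeightedMean:
    def test_equal_weights_is_plain_mean(self, rng):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 2, 2)
        fld = _field(grid, rng.uniform(0, 10, (5, 2, 2)))
        pop = PopulationRaster(grid, 2018, np.full((2, 2), 7.0),
                               np.zeros((2, 2), int), {0: 28.0})
        assert pop_weighted_mean(fld, pop) == pytest.approx(fld.values.mean())

    def test_point_mass_selects_cell(self, rng):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 2, 2)
        fld = _field(grid, rng.uniform(0, 10, (5, 2, 2)))
        counts = np.zeros((2, 2))
        counts[1, 0] = 42.0
        pop = PopulationRaster(grid, 2018, counts, np.zeros((2, 2), int),
                               {0: 42.0})
        assert pop_weighted_mean(fld, pop) == pytest.approx(
            fld.values[:, 1, 0].mean())

    def test_weighted_loop_oracle(self, rng):
        grid = GridSpec(0.0, 0.0, 1.0, 1.0, 3, 3)
        fld = _field(grid, rng.uniform(0, 30, (7, 3, 3)))
        counts = rng.uniform(0, 100, (3, 3))
        pop = PopulationRaster(grid, 2018, counts, np.zeros((3, 3), int),
                               {0: counts.sum()})
        num = den = 0.0
        for i in range(3):
            for j in range(3):
                num += counts[i, j] * fld.values[:, i, j].mean()
                den += counts[i, j]
        assert pop_weighted_mean(fld, pop) == pytest.approx(num / den, abs=1e-10)


class TestSummary:
    def test_summary_consistency(self):
        pm_total, pm_fire, o3_total, o3_fire, pop = _two_cell_setup()
        flags = flag_sfap(pm_total, pm_fire, o3_total, o3_fire)
        s = summarize_exposure(flags, pop, pm_fire, o3_fire)
        assert s.person_days == 250.0
        assert s.person_days == (s.person_days_pm_only + s.person_days_o3_only
                                 + s.person_days_both)
        assert s.people_exposed <= s.total_population
        assert s.days_per_person == pytest.approx(s.person_days / s.total_population)
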