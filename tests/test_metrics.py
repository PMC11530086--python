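"""Exposure-metric unit, example and property tests with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iohdef import metrics
from iohdef.metrics import (
    IOHDefinition,
    compute_all_definitions,
    default_registry,
    lowest_cumulative_map,
    lowest_sustained_map,
    relative_time_below,
    time_below,
)

from conftest import make_grid


def oracle_sustained(values, duration_min):
    """Threshold scan: smallest observed value held at-or-below contiguously."""
    w = int(round(4 * duration_min))
    if len(values) < w:
        return float("nan")
    for t in np.unique(values):  # ascending candidate thresholds
        below = np.asarray(values) <= t
        run = 0
        for b in below:
            run = run + 1 if b else 0
            if run >= w:
                return float(t)
    raise AssertionError("unreachable: max(values) always qualifies")


def oracle_cumulative(values, duration_min):
    """Threshold scan: smallest value with total time-at-or-below >= duration."""
    k = int(round(4 * duration_min))
    if len(values) < k:
        return float("nan")
    for t in np.unique(values):
        if int((np.asarray(values) <= t).sum()) >= k:
            return float(t)
    raise AssertionError("unreachable")


class TestWorkedExamples:
    def test_sustained_worked_grid(self, worked_grid):
        # windows of 4 ticks: maxima {80, 80, 70, 66, 75}; minimum 66
        assert lowest_sustained_map(worked_grid, 1) == 66.0

    def test_cumulative_worked_grid(self, worked_grid):
        # 4th smallest of {62, 62, 65, 66, ...}
        assert lowest_cumulative_map(worked_grid, 1) == 66.0

    def test_cumulative_interrupted_episode(self):
        grid = make_grid([50, 90, 50, 90, 50, 90, 50, 90])
        assert lowest_cumulative_map(grid, 1) == 50.0
        # the sustained metric cannot use interrupted time
        assert lowest_sustained_map(grid, 1) == 90.0

    def test_time_below_worked_grid(self, worked_grid):
        assert time_below(worked_grid, 65) == 0.5  # two ticks strictly below
        assert time_below(worked_grid, 50) == 0.0
        assert time_below(worked_grid, 100) == 0.25 * 8

    def test_relative_time_worked_grid(self, worked_grid):
        # 0.5 min below 65 over a 1.75-min record
        assert relative_time_below(worked_grid, 65) == pytest.approx(0.5 / 1.75)
        assert relative_time_below(worked_grid, 50) == 0.0
        assert relative_time_below(worked_grid, 100) == 1.0  # clipped

    @pytest.mark.parametrize("duration", [1, 3, 5])
    def test_constant_grid_returns_constant(self, duration):
        grid = make_grid(np.full(40, 70.0))
        assert lowest_sustained_map(grid, duration) == 70.0
        assert lowest_cumulative_map(grid, duration) == 70.0

    def test_short_record_yields_missing(self):
        grid = make_grid([70.0, 70.0, 70.0])
        assert np.isnan(lowest_sustained_map(grid, 1))
        assert np.isnan(lowest_cumulative_map(grid, 1))


class TestRegistry:
    def test_registry_sizes(self):
        assert len(default_registry("tables_24")) == 24
        assert len(default_registry("methods_22")) == 22

    def test_unknown_registry(self):
        with pytest.raises(ValueError, match="unknown registry"):
            default_registry("nope")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown IOH definition kind"):
            IOHDefinition("area_under", 65)

    def test_compute_all_shapes(self, worked_grid, registry24):
        vec = compute_all_definitions(worked_grid, registry24)
        assert len(vec) == 24
        assert vec["sust_1min"] == 66.0
        # 8 ticks cannot host a 3-minute window
        assert np.isnan(vec["sust_3min"])
        assert compute_all_definitions(worked_grid, []) == {}

    def test_names_stable(self):
        assert IOHDefinition("sustained_min_map", 5).name == "sust_5min"
        assert IOHDefinition("cumulative_min_map", 1).name == "cum_1min"
        assert IOHDefinition("abs_time_below", 65).name == "abs_t_lt65"
        assert IOHDefinition("rel_time_below", 80).name == "rel_t_lt80"


class TestOracleEquivalence:
    @pytest.mark.parametrize("duration", [1, 3])
    def test_matches_threshold_scan(self, random_grid_corpus, duration):
        for vals in random_grid_corpus[:150]:
            grid = make_grid(vals)
            assert lowest_sustained_map(grid, duration) == oracle_sustained(vals, duration)
            assert lowest_cumulative_map(grid, duration) == oracle_cumulative(vals, duration)

    def test_time_below_matches_counting(self, random_grid_corpus):
        for vals in random_grid_corpus[:150]:
            grid = make_grid(vals)
            for thr in (50, 65, 80):
                assert time_below(grid, thr) == 0.25 * sum(v < thr for v in vals)


class TestProperties:
    def test_monotone_in_duration(self, random_grid_corpus):
        durations = [1, 3, 5, 10]
        for vals in random_grid_corpus[:100]:
            grid = make_grid(vals)
            sus = [lowest_sustained_map(grid, d) for d in durations]
            cum = [lowest_cumulative_map(grid, d) for d in durations]
            sus = [v for v in sus if not np.isnan(v)]
            cum = [v for v in cum if not np.isnan(v)]
            assert all(a <= b for a, b in zip(sus, sus[1:]))
            assert all(a <= b for a, b in zip(cum, cum[1:]))

    def test_cumulative_dominated_by_sustained(self, random_grid_corpus):
        for vals in random_grid_corpus[:100]:
            grid = make_grid(vals)
            for d in (1, 3, 5):
                s, c = lowest_sustained_map(grid, d), lowest_cumulative_map(grid, d)
                if not (np.isnan(s) or np.isnan(c)):
                    assert c <= s

    def test_monotone_in_threshold(self, random_grid_corpus):
        thresholds = [50, 55, 60, 65, 70, 75, 80]
        for vals in random_grid_corpus[:100]:
            grid = make_grid(vals)
            tb = [time_below(grid, t) for t in thresholds]
            rb = [relative_time_below(grid, t) for t in thresholds]
            assert all(a <= b for a, b in zip(tb, tb[1:]))
            assert all(a <= b for a, b in zip(rb, rb[1:]))
            assert all(0.0 <= r <= 1.0 for r in rb)

    @given(
        st.lists(st.integers(40, 100), min_size=8, max_size=60),
        st.sampled_from([1, 2]),
        st.integers(-20, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_translation_equivariance(self, vals, duration, shift):
        grid = make_grid(vals)
        shifted = make_grid(np.asarray(vals, float) + shift)
        assert lowest_sustained_map(shifted, duration) == pytest.approx(
            lowest_sustained_map(grid, duration) + shift
        )
        assert lowest_cumulative_map(shifted, duration) == pytest.approx(
            lowest_cumulative_map(grid, duration) + shift
        )

    @given(st.lists(st.integers(40, 100), min_size=4, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_sustained_value_is_attained(self, vals):
        grid = make_grid(vals)
        s = lowest_sustained_map(grid, 1)
        c = lowest_cumulative_map(grid, 1)
        assert s in set(float(v) for v in vals)
        assert c in set(float(v) for v in vals)
        assert min(vals) <= c <= s <= max(vals)
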