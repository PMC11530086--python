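"""Winsorization, splines, LOS trimming and model-matrix assembly."""

import numpy as np
import pytest

from iohdef import pipeline
from iohdef.design import (
    ModelSettings,
    build_model_matrix,
    natural_spline_basis,
    trim_and_log_los,
    winsorize,
    zero_spike_indicator,
)
from iohdef.metrics import IOHDefinition, default_registry


@pytest.fixture(scope="module")
def cohort_table(small_cohort):
    feats, _, _ = pipeline.compute_features(
        small_cohort.public_vitals(), default_registry()
    )
    return small_cohort.cohort_table.merge(feats, on="patient_id")


class TestWinsorize:
    def test_caps_upper_tail_only(self):
        vals = np.arange(1.0, 101.0)
        capped, cap = winsorize(vals, 0.99)
        assert cap == pytest.approx(np.quantile(vals, 0.99))
        assert (capped != vals).sum() == 1  # only the maximum moves
        assert capped.min() == vals.min()

    def test_constant_unchanged(self):
        capped, _ = winsorize(np.full(10, 7.0))
        assert np.array_equal(capped, np.full(10, 7.0))

    def test_idempotent(self):
        vals = np.random.default_rng(0).exponential(size=200)
        once, cap = winsorize(vals)
        twice, _ = winsorize(once, cap=cap)
        assert np.array_equal(once, twice)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            winsorize(np.array([np.nan, 1.0]))


class TestZeroSpike:
    def test_indicator_values(self):
        out = zero_spike_indicator(np.array([0.0, 0.5, 0.0, 2.0]), "abs_time_below")
        assert np.array_equal(out, [1, 0, 1, 0])
        assert zero_spike_indicator(np.array([1.0, 2.0]), "rel_time_below").sum() == 0

    def test_rejected_for_episode_kinds(self):
        with pytest.raises(ValueError, match="time-below"):
            zero_spike_indicator(np.array([0.0, 1.0]), "sustained_min_map")


class TestNaturalSpline:
    @pytest.mark.parametrize("df", [2, 3, 4])
    def test_dimension(self, df):
        x = np.linspace(0, 1, 50)
        basis, knots, fallback = natural_spline_basis(x, df)
        assert basis.shape == (50, df)
        assert not fallback
        assert knots.size == df + 1

    def test_linear_beyond_boundaries(self):
        x = np.random.default_rng(1).uniform(0, 1, 200)
        _, knots, _ = natural_spline_basis(x, 3)
        # evaluate far outside the boundary: second differences vanish
        xs = np.array([2.0, 2.5, 3.0, 3.5])
        basis, _, _ = natural_spline_basis(xs, 3, knots=knots)
        second = np.diff(basis, n=2, axis=0)
        assert np.max(np.abs(second)) < 1e-8

    def test_recovers_straight_line(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-3, 5, 300)
        y = 1.7 * x - 0.4
        basis, _, _ = natural_spline_basis(x, 3)
        X = np.column_stack([np.ones_like(x), basis])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        assert np.max(np.abs(resid)) < 1e-6 * (y.max() - y.min())

    def test_degenerate_falls_back_to_linear(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="linear"):
            basis, knots, fallback = natural_spline_basis(x, 3)
        assert fallback and basis.shape[1] == 1


class TestTrimAndLog:
    def test_death_removed_first(self):
        los = np.ones(100) * 5.0
        died = np.zeros(100, bool)
        died[37] = True
        logs, kept = trim_and_log_los(los, died, 0.01)
        assert kept.sum() == 99 and not kept[37]
        assert np.isfinite(logs).all()

    def test_ceil_rule_without_deaths(self):
        rng = np.random.default_rng(3)
        los = rng.exponential(5, size=200) + 0.5
        logs, kept = trim_and_log_los(los, np.zeros(200, bool), 0.01)
        assert (~kept).sum() == 2  # ceil(0.01 * 200)
        assert los[~kept].min() >= los[kept].max()

    def test_log_values(self):
        logs, kept = trim_and_log_los(
            np.array([np.e, np.e**2, 1.0]), np.zeros(3, bool), 0.01
        )
        assert np.allclose(sorted(logs), [0.0, 1.0])  # e^2 trimmed as largest

    def test_too_many_deaths_is_an_error(self):
        los = np.ones(100) * 3.0
        died = np.zeros(100, bool)
        died[:5] = True
        with pytest.raises(ValueError, match="exceed the trim fraction"):
            trim_and_log_los(los, died, 0.01)

    @pytest.mark.parametrize("frac", [0.0, 0.5, -0.1])
    def test_trim_fraction_domain(self, frac):
        with pytest.raises(ValueError):
            trim_and_log_los(np.ones(10), np.zeros(10, bool), frac)


class TestModelMatrix:
    def test_time_below_block_has_indicator(self, cohort_table):
        mm = build_model_matrix(
            cohort_table, IOHDefinition("rel_time_below", 80), "mortality"
        )
        ioh = mm.groups["ioh"]
        assert "rel_t_lt80_is_zero" in ioh
        assert len([c for c in ioh if "_ns" in c or c.endswith("_lin")]) >= 1

    def test_episode_block_has_no_indicator(self, cohort_table):
        mm = build_model_matrix(
            cohort_table, IOHDefinition("sustained_min_map", 1), "hlos"
        )
        assert all(not c.endswith("_is_zero") for c in mm.groups["ioh"])
        assert len(mm.groups["ioh"]) == 3

    def test_covariate_blocks_present(self, cohort_table):
        mm = build_model_matrix(
            cohort_table, IOHDefinition("sustained_min_map", 1), "mortality"
        )
        assert set(mm.groups) == {
            "ioh", "sex", "specialty", "asa", "age", "bmi", "duration",
            "time_to_surgery", "comorbidity", "intercept",
        }
        assert len(mm.groups["specialty"]) == 5  # 6 categories, 1 reference
        assert len(mm.groups["asa"]) == 3  # reference ASA 2
        assert not mm.X.isna().any().any()

    def test_nested_row_counts(self, cohort_table):
        d = IOHDefinition("sustained_min_map", 1)
        mm_mort = build_model_matrix(cohort_table, d, "mortality")
        mm_hlos = build_model_matrix(cohort_table, d, "hlos")
        mm_pacu = build_model_matrix(cohort_table, d, "pacu")
        trimmed = next(
            e["n"] for e in mm_hlos.exclusions if e["reason"].startswith("trimmed")
        )
        assert mm_hlos.n == mm_mort.n - trimmed
        n_icu = int(cohort_table["icu_direct"].sum())
        assert mm_pacu.n <= mm_mort.n - n_icu
        assert set(mm_hlos.patient_ids) <= set(mm_mort.patient_ids)
        assert set(mm_pacu.patient_ids) <= set(mm_mort.patient_ids)

    def test_all_icu_is_empty_analysis_set(self, cohort_table):
        all_icu = cohort_table.copy()
        all_icu["icu_direct"] = 1
        with pytest.raises(ValueError, match="empty analysis set"):
            build_model_matrix(all_icu, IOHDefinition("sustained_min_map", 1), "pacu")

    def test_unknown_outcome(self, cohort_table):
        with pytest.raises(ValueError, match="unknown outcome"):
            build_model_matrix(
                cohort_table, IOHDefinition("sustained_min_map", 1), "icu"
            )

    def test_deterministic(self, cohort_table):
        d = IOHDefinition("rel_time_below", 80)
        a = build_model_matrix(cohort_table, d, "mortality")
        b = build_model_matrix(cohort_table, d, "mortality")
        assert a.X.equals(b.X) and np.array_equal(a.y, b.y)

    def test_univariable_setting(self, cohort_table):
        mm = build_model_matrix(
            cohort_table, IOHDefinition("abs_time_below", 65), "mortality",
            ModelSettings(univariable=True),
        )
        assert set(mm.groups) == {"ioh", "intercept"}
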