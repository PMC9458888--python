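"""Model-frame construction: disaggregation, standardization, coding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diaryreact import designs
from diaryreact.preprocess import (
    build_model_frame,
    build_time_covariates,
    code_binary,
    person_disaggregate,
    product_name,
    standardize_long,
    transform_bounds,
)


class TestDisaggregate:
    def test_two_values(self):
        bp, wp = person_disaggregate(np.array([2.0, 4.0]), np.array([0, 0]))
        assert bp.tolist() == [3.0, 3.0]
        assert wp.tolist() == [-1.0, 1.0]

    def test_constant_person_has_zero_wp(self):
        bp, wp = person_disaggregate(np.array([5.0, 5.0, 5.0]), np.array([0, 0, 0]))
        assert np.all(wp == 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_and_zero_sum(self, seed):
        rng = np.random.default_rng(seed)
        n_persons = rng.integers(2, 8)
        counts = rng.integers(1, 6, n_persons)
        idx = np.repeat(np.arange(n_persons), counts)
        x = rng.normal(size=len(idx))
        bp, wp = person_disaggregate(x, idx)
        assert np.allclose(bp + wp, x)
        for j in range(n_persons):
            assert np.sum(wp[idx == j]) == pytest.approx(0, abs=1e-9)


class TestStandardize:
    def test_population_sd_convention(self):
        z, m, sd = standardize_long(np.array([0.0, 2.0]))
        assert (m, sd) == (1.0, 1.0)
        assert z.tolist() == [-1.0, 1.0]

    def test_round_trip_is_affine(self, rng):
        x = rng.normal(3, 2, 100)
        z, m, sd = standardize_long(x)
        assert np.allclose(z * sd + m, x)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize_long(np.full(5, 2.0))


class TestCodeBinary:
    def test_gender_coding(self):
        codes, mapping = code_binary(np.array([0, 1, 1, 0]), positive_value=1)
        assert codes.tolist() == [-1.0, 1.0, 1.0, -1.0]
        assert mapping == {0: -1, 1: 1}

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            code_binary(np.array([1, 1, 1]))

    def test_three_levels_rejected(self):
        with pytest.raises(ValueError):
            code_binary(np.array([0, 1, 2]))


def test_time_covariates_raw_scale():
    day, day_sq = build_time_covariates(np.array([0, 3, 9]))
    assert day.tolist() == [0.0, 3.0, 9.0]
    assert day_sq.tolist() == [0.0, 9.0, 81.0]


def test_transform_bounds_affine():
    lo, hi = transform_bounds((1.0, 5.0), 2.5, 1.28)
    assert lo == pytest.approx(-1.171875)
    assert hi == pytest.approx(1.953125)
    assert lo < hi
    assert transform_bounds((2.5, 5.0), 2.5, 1.28)[0] == 0.0


def test_product_name_handles_powers():
    assert product_name(("a", "b")) == "a:b"
    assert product_name(("s", "s")) == "s^2"
    assert product_name(("l", "s", "s")) == "l:s^2"


class TestBuildModelFrame:
    def test_column_schema_matches_reporting_order(self, na_frame):
        assert na_frame.columns == [
            "intercept", "age", "female", "tertiary_educated",
            "not_in_labor_force", "physical_functioning", "day", "day_sq",
            "weekend", "bp_aarc_gains", "bp_aarc_losses", "bp_stress_severity",
            "wp_aarc_gains", "wp_aarc_losses", "wp_stress_severity",
            "wp_aarc_gains:wp_aarc_losses", "wp_aarc_gains:wp_stress_severity",
            "wp_aarc_losses:wp_stress_severity",
            "wp_aarc_gains:wp_aarc_losses:wp_stress_severity",
        ]

    def test_no_missing_values(self, na_frame):
        assert np.all(np.isfinite(na_frame.X))
        assert np.all(np.isfinite(na_frame.y))

    def test_wp_columns_sum_to_zero_within_person(self, na_frame):
        for c in ("wp_aarc_gains", "wp_aarc_losses", "wp_stress_severity"):
            wp = na_frame.column(c)
            sums = np.bincount(na_frame.person_index, weights=wp)
            assert np.allclose(sums, 0, atol=1e-9)

    def test_bp_plus_wp_reconstructs_standardized_variable(self, na_dataset, na_frame):
        table, _ = na_dataset
        raw = table.frame["aarc_losses"].to_numpy()
        z, _, _ = standardize_long(raw)
        total = na_frame.column("bp_aarc_losses") + na_frame.column("wp_aarc_losses")
        assert np.allclose(total, z)

    def test_products_recompute_from_parents(self, na_frame):
        g = na_frame.column("wp_aarc_gains")
        s = na_frame.column("wp_stress_severity")
        assert np.allclose(na_frame.column("wp_aarc_gains:wp_stress_severity"), g * s)

    def test_binary_columns_are_plus_minus_one(self, na_frame):
        for c in ("female", "tertiary_educated", "not_in_labor_force", "weekend"):
            assert set(np.unique(na_frame.column(c))) <= {-1.0, 1.0}

    def test_censor_codes_match_bound_counts(self, na_frame):
        lo, hi = na_frame.bounds
        at_lo = np.isclose(na_frame.y, lo).sum()
        assert (na_frame.censor_code == -1).sum() == at_lo
        assert (na_frame.censor_code == 1).sum() == 0  # upper bound is +inf

    def test_idempotent(self, na_dataset):
        table, params = na_dataset
        a = build_model_frame(table, params.design, outcome_moments=params.outcome_moments)
        b = build_model_frame(table, params.design, outcome_moments=params.outcome_moments)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.censor_code, b.censor_code)

    def test_quadratic_design_adds_expected_columns(self, na_dataset):
        table, params = na_dataset
        quad = params.design.with_quadratic_stress()
        frame = build_model_frame(table, quad, outcome_moments=params.outcome_moments)
        s = frame.column("wp_stress_severity")
        assert np.allclose(frame.column("wp_stress_severity^2"), s * s)
        assert "wp_aarc_losses:wp_stress_severity^2" in frame.columns

    def test_standardize_outcome_from_sample_when_no_moments(self, na_dataset):
        table, params = na_dataset
        frame = build_model_frame(table, designs.vitality_design())
        assert frame.y.mean() == pytest.approx(0, abs=1e-9)
        assert frame.y.std(ddof=0) == pytest.approx(1)
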