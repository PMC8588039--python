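"""Confidence curves, AUCO, fraction MSEs, and predictive-quality metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hvlforest import (
    InputError,
    auco,
    confidence_curve,
    evaluate_measures,
    mse,
    mse_at_fractions,
    oracle_curve,
    pearson_r,
    r_squared,
    relative_auco,
)

RESIDUALS_3 = np.array([3.0, 1.0, 2.0])


def naive_curve(residuals, um):
    """From-scratch MSE recomputation after each removal (independent oracle)."""
    order = np.argsort(-np.asarray(um), kind="stable")
    sq = np.asarray(residuals, dtype=float)[order] ** 2
    return np.array([np.mean(sq[k:]) for k in range(len(sq))])


finite_floats = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestConfidenceCurve:
    def test_perfectly_ordered_um_reproduces_hand_curve(self):
        curve = confidence_curve(RESIDUALS_3, [0.9, 0.1, 0.5])
        assert np.allclose(curve.mse_at_k, [14 / 3, 2.5, 1.0])
        assert curve.mse0 == pytest.approx(14 / 3)

    def test_constant_um_removes_in_input_order(self):
        curve = confidence_curve(RESIDUALS_3, [1.0, 1.0, 1.0])
        assert np.allclose(curve.mse_at_k, naive_curve(RESIDUALS_3, [0, 0, 0]))
        assert np.allclose(curve.mse_at_k, [14 / 3, 2.5, 4.0])

    def test_randomized_tie_break_reorders_only_within_ties(self):
        residuals = np.array([3.0, 1.0, 2.0, 0.5])
        um = np.array([0.9, 0.5, 0.5, 0.1])
        stable = confidence_curve(residuals, um)
        for seed in range(5):
            jittered = confidence_curve(residuals, um, tie_seed=seed)
            # endpoints bracket the tied block, so they never move
            assert jittered.mse_at_k[0] == stable.mse_at_k[0]
            assert jittered.mse_at_k[1] == stable.mse_at_k[1]
            assert jittered.mse_at_k[3] == stable.mse_at_k[3]
        # some seed must swap the tied pair (residuals 1 and 2 differ)
        curves = {
            tuple(confidence_curve(residuals, um, tie_seed=s).mse_at_k)
            for s in range(10)
        }
        assert len(curves) == 2

    def test_equal_residuals_give_flat_curve(self):
        curve = confidence_curve([2.0] * 5, np.arange(5))
        assert np.allclose(curve.mse_at_k, 4.0)

    @pytest.mark.parametrize(
        "residuals, um, err",
        [
            ([1, 2], [1], "length"),
            ([1], [1], "at least 2"),
            ([1, np.nan], [1, 2], "finite"),
            ([1, 2], [np.inf, 0], "finite"),
        ],
    )
    def test_contract_violations(self, residuals, um, err):
        with pytest.raises(InputError, match=err):
            confidence_curve(residuals, um)

    @given(
        st.lists(finite_floats, min_size=2, max_size=60),
        st.randoms(use_true_random=False),
    )
    def test_incremental_matches_naive_recomputation(self, residuals, rnd):
        um = [rnd.random() for _ in residuals]
        curve = confidence_curve(residuals, um)
        expected = naive_curve(residuals, um)
        assert np.allclose(curve.mse_at_k, expected, rtol=1e-9, atol=1e-12)

    @given(st.lists(finite_floats, min_size=2, max_size=60))
    def test_scale_equivariance(self, residuals):
        um = np.arange(len(residuals), dtype=float)
        base = confidence_curve(residuals, um)
        scaled = confidence_curve(3.0 * np.asarray(residuals), um)
        assert np.allclose(scaled.mse_at_k, 9.0 * base.mse_at_k, rtol=1e-9, atol=1e-9)


class TestOracleCurve:
    def test_hand_examples(self):
        assert np.allclose(oracle_curve(RESIDUALS_3).mse_at_k, [14 / 3, 2.5, 1.0])
        assert np.allclose(oracle_curve([0.0, 0.0, 5.0]).mse_at_k, [25 / 3, 0.0, 0.0])

    @given(st.lists(finite_floats, min_size=2, max_size=100))
    def test_monotone_non_increasing(self, residuals):
        curve = oracle_curve(residuals).mse_at_k
        assert (np.diff(curve) <= 1e-9 * np.maximum(curve[:-1], 1)).all()

    @given(
        st.lists(finite_floats, min_size=2, max_size=60),
        st.randoms(use_true_random=False),
    )
    def test_oracle_dominates_any_measure_pointwise(self, residuals, rnd):
        um = [rnd.random() for _ in residuals]
        ideal = oracle_curve(residuals).mse_at_k
        other = confidence_curve(residuals, um).mse_at_k
        assert (ideal <= other + 1e-9 * np.maximum(np.abs(other), 1)).all()


class TestAuco:
    def test_anti_ordered_hand_example(self):
        um_curve = confidence_curve(RESIDUALS_3, [0.1, 0.9, 0.5])
        assert auco(um_curve, oracle_curve(RESIDUALS_3), coverage=0.5) == pytest.approx(4.0)

    def test_oracle_against_itself_is_zero(self):
        ideal = oracle_curve(RESIDUALS_3)
        assert auco(confidence_curve(RESIDUALS_3, np.abs(RESIDUALS_3)), ideal) == pytest.approx(0.0)

    def test_growing_coverage_never_shrinks_area(self):
        rng = np.random.default_rng(4)
        residuals, um = rng.normal(size=200), rng.random(200)
        ideal = oracle_curve(residuals)
        curve = confidence_curve(residuals, um)
        areas = [auco(curve, ideal, c) for c in (0.1, 0.3, 0.5, 0.9, 1.0)]
        assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_mismatched_sizes_raise(self):
        with pytest.raises(InputError, match="different sizes"):
            auco(oracle_curve([1, 2]), oracle_curve([1, 2, 3]))


class TestMseAtFractions:
    def test_hand_indexing_on_three_points(self):
        table = mse_at_fractions(oracle_curve(RESIDUALS_3), fractions=(0.0, 0.5))
        assert table[0.0] == pytest.approx(14 / 3)
        assert table[0.5] == pytest.approx(2.5)  # k = floor(1.5) = 1

    def test_deep_fraction_keeps_most_certain_tail(self):
        residuals = np.arange(100, dtype=float)  # |residual| increases with index
        curve = confidence_curve(residuals, residuals)
        # f=0.9 -> k=90: the 10 smallest residuals 0..9 remain
        assert mse_at_fractions(curve, fractions=(0.9,))[0.9] == pytest.approx(
            np.mean(np.arange(10.0) ** 2)
        )

    def test_fraction_one_rejected(self):
        with pytest.raises(InputError, match="fraction"):
            mse_at_fractions(oracle_curve(RESIDUALS_3), fractions=(1.0,))


class TestScalarMetrics:
    def test_relative_auco(self):
        assert relative_auco(2.0, 1.6) == pytest.approx(125.0)
        assert relative_auco(0.0, 1.0) == 0.0
        assert relative_auco(1.0, 1.0) == 100.0
        with pytest.raises(InputError):
            relative_auco(1.0, 0.0)

    def test_pearson(self):
        u = np.array([1.0, 2.0, 3.0])
        assert pearson_r(u, u) == pytest.approx(1.0)
        assert pearson_r(u, -u) == pytest.approx(-1.0)
        assert pearson_r(u, [1.0, 2.0, 4.0]) == pytest.approx(0.981980506, rel=1e-6)
        with pytest.raises(InputError, match="constant"):
            pearson_r(u, [1.0, 1.0, 1.0])

    def test_mse(self):
        assert mse([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)
        assert mse([5.0], [2.0]) == pytest.approx(9.0)
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_r_squared_whole_dataset_mean_convention(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r_squared(y, y, ybar=1.0) == pytest.approx(1.0)
        assert r_squared(y, [1.0, 1.0, 1.0], ybar=1.0) == pytest.approx(0.0)
        assert r_squared(y, [0.0, 1.0, 1.0], ybar=1.0) == pytest.approx(0.5)
        with pytest.raises(InputError, match="undefined"):
            r_squared([1.0, 1.0], [0.0, 0.0], ybar=1.0)


def test_evaluate_measures_report_structure():
    rng = np.random.default_rng(0)
    residuals = rng.normal(size=120)
    ums = {"hvl": np.abs(residuals) + rng.normal(0, 0.5, 120), "sdep": rng.random(120)}
    report = evaluate_measures(residuals, ums)
    assert set(report.auco50) == {"hvl", "sdep"}
    assert report.auco50["hvl"] >= 0 and report.auco50["sdep"] >= 0
    assert report.relative_auco50 == pytest.approx(
        100 * report.auco50["hvl"] / report.auco50["sdep"]
    )
    # MSE0 is shared by every measure's fraction table
    for measure in ums:
        assert report.mse_at_fraction[measure][0.0] == pytest.approx(report.mse0)
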