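import itertools

import numpy as np
import pytest

from facdeg import (
    Factor,
    attach_responses,
    build_full_factorial,
    default_pool,
    estimate_coefficients,
    predict,
    reduce_model,
    screen_effects,
    yates_algorithm,
)
from facdeg._fmt import round_half_even
from facdeg.effects import ExtrapolationWarning, all_terms, model_matrix, parse_term_label, term_label
from tests.conftest import ALKALI_RESPONSES, PUBLISHED_COEFFS


def _random_design(k, rng):
    d = build_full_factorial([Factor(f"x{j}", 0, 1) for j in range(k)])
    return attach_responses(d, rng.normal(size=2**k))


class TestEstimateCoefficients:
    def test_alkali_raw_coefficients(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        raw = {
            "1": 13.625, "X1": 1.875, "X2": 4.125, "X3": 11.125,
            "X1X2": 0.875, "X2X3": 1.625, "X1X3": 0.375, "X1X2X3": -0.625,
        }
        for label, expected in raw.items():
            assert m.coefficient(label) == pytest.approx(expected, abs=1e-12)

    def test_alkali_published_two_decimal_coefficients(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        for label, expected in PUBLISHED_COEFFS.items():
            assert round_half_even(m.coefficient(label)) == expected

    def test_constant_responses(self, alkali_factors):
        d = attach_responses(build_full_factorial(alkali_factors), [7.5] * 8)
        m = estimate_coefficients(d)
        assert m.coefficient("1") == pytest.approx(7.5)
        assert np.allclose(m.coefficients[1:], 0.0, atol=1e-14)

    def test_matches_dense_linear_solve_oracle(self):
        # oracle: solve the full 8x8 linear system directly
        rng = np.random.default_rng(7)
        terms = all_terms(3)
        for _ in range(20):
            d = _random_design(3, rng)
            X = model_matrix(d.runs, terms).astype(float)
            oracle = np.linalg.solve(X, d.responses)
            m = estimate_coefficients(d)
            np.testing.assert_allclose(m.coefficients, oracle, atol=1e-10)

    def test_requires_responses(self, alkali_factors):
        with pytest.raises(ValueError, match="responses"):
            estimate_coefficients(build_full_factorial(alkali_factors))

    def test_saturated_fit_reproduces_every_observation(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        for run, y in zip(alkali_design.runs, alkali_design.responses):
            assert predict(m, run.astype(float)) == pytest.approx(y, abs=1e-12)


class TestYates:
    def test_alkali_contrasts_over_8_match_coefficients(self):
        contrasts = yates_algorithm(ALKALI_RESPONSES)
        assert round_half_even(contrasts[4] / 8) == 11.12  # power term
        np.testing.assert_allclose(
            contrasts / 8, [13.625, 1.875, 4.125, 0.875, 11.125, 0.375, 1.625, -0.625]
        )

    def test_all_zero_responses(self):
        np.testing.assert_array_equal(yates_algorithm(np.zeros(8)), np.zeros(8))

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_agrees_with_contrast_formula(self, k):
        # oracle: estimate_coefficients (independent contrast computation)
        rng = np.random.default_rng(100 + k)
        for _ in range(10):
            d = _random_design(k, rng)
            m = estimate_coefficients(d)
            np.testing.assert_allclose(
                yates_algorithm(d.responses) / 2**k, m.coefficients, atol=1e-10
            )

    def test_rejects_non_power_of_two(self):
        with pytest.raises(ValueError, match="power of two"):
            yates_algorithm([1.0, 2.0, 3.0])


class TestScreenEffects:
    def test_alkali_ranking_power_then_time(self, alkali_design):
        scr = screen_effects(alkali_design, pool=["X1X2", "X1X3", "X1X2X3"])
        f = dict(zip(scr.labels, scr.f_statistics))
        assert f["X3"] > f["X2"] > f["X1"]
        assert np.nanargmax(scr.f_statistics) == scr.labels.index("X3")
        sig = dict(zip(scr.labels, scr.significant))
        assert sig["X3"] and sig["X2"]

    def test_default_pool_is_inert_interactions(self, alkali_design):
        pool = default_pool(alkali_design)
        assert sorted(term_label(t) for t in pool) == ["X1X2", "X1X2X3", "X1X3"]

    def test_pure_single_factor_signal(self, alkali_factors):
        d = build_full_factorial(alkali_factors)
        y = 10.0 + 5.0 * d.runs[:, 2]
        d = attach_responses(d, y)
        scr = screen_effects(d, pool=["X1X2", "X1X3", "X1X2X3"])
        ss = dict(zip(scr.labels, scr.sums_of_squares))
        assert ss["X3"] > 0
        for label, v in ss.items():
            if label != "X3":
                assert v == pytest.approx(0.0, abs=1e-18)

    def test_ss_decomposition_oracle(self):
        # oracle: direct corrected total sum of squares
        rng = np.random.default_rng(11)
        for _ in range(50):
            d = _random_design(3, rng)
            scr = screen_effects(d, pool=["X1X2X3"])
            total = float(((d.responses - d.responses.mean()) ** 2).sum())
            assert scr.sums_of_squares.sum() == pytest.approx(total, rel=1e-12)

    def test_ss_invariant_to_constant_shift(self, alkali_design, alkali_factors):
        scr1 = screen_effects(alkali_design, pool=["X1X2X3"])
        shifted = attach_responses(
            build_full_factorial(alkali_factors), alkali_design.responses + 123.0
        )
        scr2 = screen_effects(shifted, pool=["X1X2X3"])
        np.testing.assert_allclose(scr1.sums_of_squares, scr2.sums_of_squares, atol=1e-9)

    def test_pool_cannot_exhaust_all_terms(self, alkali_design):
        every = [term_label(t) for t in all_terms(3) if t]
        with pytest.raises(ValueError, match="exhausts"):
            screen_effects(alkali_design, pool=every)

    def test_zero_pooled_ms_flags_f_undefined(self, alkali_factors):
        d = build_full_factorial(alkali_factors)
        d = attach_responses(d, 10.0 + 5.0 * d.runs[:, 2])
        scr = screen_effects(d, pool=["X1X2", "X1X3", "X1X2X3"])
        assert not scr.f_defined
        assert np.isnan(scr.f_statistics).all()
        assert not scr.significant.any()

    def test_f_statistic_absent_for_pooled_terms(self, alkali_design):
        scr = screen_effects(alkali_design, pool=["X1X2", "X1X3", "X1X2X3"])
        for label, f in zip(scr.labels, scr.f_statistics):
            if parse_term_label(label) in scr.pooled_terms:
                assert np.isnan(f)
            else:
                assert np.isfinite(f)


class TestReduceModel:
    def test_drop_naoh_gives_published_reduced_terms(self, alkali_design):
        m = reduce_model(estimate_coefficients(alkali_design), ["naoh"])
        assert m.labels == ["1", "X2", "X3", "X2X3"]
        np.testing.assert_allclose(m.coefficients, [13.625, 4.125, 11.125, 1.625])
        assert [round_half_even(c) for c in m.coefficients] == [13.62, 4.12, 11.12, 1.62]

    def test_drop_nothing_is_identity(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        m2 = reduce_model(m, [])
        assert m2.terms == m.terms
        np.testing.assert_array_equal(m2.coefficients, m.coefficients)

    def test_least_squares_refit_oracle(self, alkali_design):
        # orthogonality guarantees the reduced coefficients equal a
        # least-squares refit of only the retained terms
        m = reduce_model(estimate_coefficients(alkali_design), ["naoh"])
        X = model_matrix(alkali_design.runs, m.terms).astype(float)
        refit, *_ = np.linalg.lstsq(X, alkali_design.responses, rcond=None)
        np.testing.assert_allclose(m.coefficients, refit, atol=1e-10)

    def test_cannot_drop_all_factors(self, alkali_design):
        with pytest.raises(ValueError, match="every factor"):
            reduce_model(estimate_coefficients(alkali_design), ["naoh", "time", "power"])


class TestPredict:
    def test_saturated_interpolates_all_high_corner(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        assert predict(m, [1.0, 1.0, 1.0]) == pytest.approx(33.0, abs=1e-12)

    def test_center_point_returns_intercept(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        assert predict(m, [0.0, 0.0, 0.0]) == pytest.approx(m.coefficient("1"))

    def test_published_reduced_model_at_high_corner(self, reduced_published_model):
        val = predict(reduced_published_model, [0.0, 1.0, 1.0])
        assert val == pytest.approx(13.62 + 4.12 + 11.12 + 1.62)
        assert val == pytest.approx(30.48)

    def test_dimension_mismatch(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        with pytest.raises(ValueError, match="length"):
            predict(m, [0.0, 0.0])

    def test_extrapolation_warns(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        with pytest.warns(ExtrapolationWarning):
            predict(m, [2.0, 0.0, 0.0])

    def test_mapping_point(self, alkali_design):
        m = estimate_coefficients(alkali_design)
        assert predict(m, {"power": 1.0}) == pytest.approx(13.625 + 11.125)


class TestThreeWayAgreement:
    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_yates_contrast_least_squares(self, k):
        rng = np.random.default_rng(500 + k)
        terms = all_terms(k)
        for _ in range(5):
            d = _random_design(k, rng)
            contrast = estimate_coefficients(d).coefficients
            via_yates = yates_algorithm(d.responses) / 2**k
            X = model_matrix(d.runs, terms).astype(float)
            via_lstsq, *_ = np.linalg.lstsq(X, d.responses, rcond=None)
            np.testing.assert_allclose(via_yates, contrast, atol=1e-10)
            np.testing.assert_allclose(via_lstsq, contrast, atol=1e-8)
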