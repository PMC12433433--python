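"""Scoring matrices, category probabilities and parameter counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respstyles import (
    ItemParameters,
    ModelSpec,
    build_scoring_matrix,
    category_probabilities,
    count_free_parameters,
    probability_curves,
)


class TestScoringMatrices:
    def test_null_row_is_linear(self):
        sm = build_scoring_matrix("null", 5, 1)
        assert sm.values.shape == (1, 5)
        np.testing.assert_array_equal(sm.values[0], [0, 1, 2, 3, 4])

    def test_bipolar_rows(self):
        sm = build_scoring_matrix("ers_mrs", 5, 1)
        np.testing.assert_array_equal(sm.values,
                                      [[0, 1, 2, 3, 4], [2, 1, 0, 1, 2]])

    def test_two_dimensional_rows(self):
        sm = build_scoring_matrix("ers_plus_mrs", 5, 1)
        np.testing.assert_array_equal(
            sm.values,
            [[0, 1, 2, 3, 4], [1, 0, 0, 0, 1], [0, 0, 1, 0, 0]])

    def test_two_substantive_dimensions_duplicate_the_linear_row(self):
        sm = build_scoring_matrix("ers_mrs", 5, 2)
        assert sm.values.shape == (3, 5)
        np.testing.assert_array_equal(sm.values[0], sm.values[1])

    def test_general_odd_k(self):
        sm = build_scoring_matrix("ers_plus_mrs", 7, 1)
        np.testing.assert_array_equal(sm.values[1], [1, 0, 0, 0, 0, 0, 1])
        np.testing.assert_array_equal(sm.values[2], [0, 0, 0, 1, 0, 0, 0])
        bipolar = build_scoring_matrix("ers_mrs", 7, 1)
        np.testing.assert_array_equal(bipolar.values[1], [3, 2, 1, 0, 1, 2, 3])

    def test_even_k_with_midpoint_style_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_scoring_matrix("ers_mrs", 4, 1)
        with pytest.raises(ValueError, match="odd"):
            build_scoring_matrix("ers_plus_mrs", 6, 1)
        # even K is fine when no midpoint style is modelled
        assert build_scoring_matrix("null", 4, 1).n_categories == 4


class TestCategoryProbabilities:
    def test_zero_parameters_give_uniform(self):
        sm = build_scoring_matrix("null", 5, 1)
        item = ItemParameters(np.zeros(1), np.zeros(5))
        np.testing.assert_allclose(
            category_probabilities(np.zeros(1), item, sm), np.full(5, 0.2))

    def test_response_style_cancels_generating_intercepts(self):
        # theta_RS = +1 with unit RS slope contributes (2,1,0,1,2), exactly
        # cancelling the (-2,-1,0,-1,-2) intercepts: the result is uniform
        sm = build_scoring_matrix("ers_mrs", 5, 1)
        item = ItemParameters([1.0, 1.0], [-2, -1, 0, -1, -2])
        p = category_probabilities(np.array([0.0, 1.0]), item, sm)
        np.testing.assert_allclose(p, np.full(5, 0.2), atol=1e-12)

    def test_softmax_of_symmetric_intercepts(self):
        sm = build_scoring_matrix("null", 5, 1)
        item = ItemParameters(np.zeros(1), [0, 1, 2, 1, 0])
        expected = np.exp([0, 1, 2, 1, 0]) / np.exp([0, 1, 2, 1, 0]).sum()
        p = category_probabilities(np.zeros(1), item, sm)
        np.testing.assert_allclose(p, expected, atol=5e-6)
        np.testing.assert_allclose(
            p, [0.06745, 0.18336, 0.49839, 0.18336, 0.06745], atol=1e-5)

    def test_dimension_mismatch_rejected(self):
        sm = build_scoring_matrix("ers_mrs", 5, 1)
        item = ItemParameters([1.0, 1.0], np.zeros(5))
        with pytest.raises(ValueError):
            category_probabilities(np.zeros(1), item, sm)

    @settings(deadline=None, derandomize=True)
    @given(theta=st.floats(-4, 4), slope=st.floats(0.1, 3),
           shift=st.floats(-5, 5))
    def test_normalization_and_location_invariance(self, theta, slope, shift):
        """Probabilities sum to one, and shifting all intercepts by a
        constant changes nothing (softmax location invariance)."""
        sm = build_scoring_matrix("null", 5, 1)
        base = np.array([-2.0, -1.0, 0.0, -1.0, -2.0])
        p = category_probabilities(np.array([theta]),
                                   ItemParameters([slope], base), sm)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all((p > 0) & (p < 1))
        q = category_probabilities(np.array([theta]),
                                   ItemParameters([slope], base + shift), sm)
        np.testing.assert_allclose(p, q, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(theta=st.floats(-3, 3), slope=st.floats(0.2, 2.5))
    def test_mirror_symmetry_with_symmetric_intercepts(self, theta, slope):
        """With symmetric intercepts and no response style,
        P(Y=k | theta) = P(Y=K-1-k | -theta)."""
        sm = build_scoring_matrix("null", 5, 1)
        item = ItemParameters([slope], [-2, -1, 0, -1, -2])
        p_pos = category_probabilities(np.array([theta]), item, sm)
        p_neg = category_probabilities(np.array([-theta]), item, sm)
        np.testing.assert_allclose(p_pos, p_neg[::-1], atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(theta_sub=st.floats(-3, 3), theta_rs=st.floats(-3, 3),
           a_sub=st.floats(0.2, 2.5), a_rs=st.floats(0.2, 2.5))
    def test_bipolar_equals_antiperfect_two_dimensional(self, theta_sub,
                                                        theta_rs, a_sub, a_rs):
        """A bipolar ERS/MRS item equals a two-dimensional item with equal
        ERS and MRS slopes evaluated at theta_ERS = -theta_MRS, because the
        bipolar scoring row is the ERS row minus the MRS row plus a constant
        that cancels in the softmax."""
        intercepts = np.array([-2.0, -1.0, 0.0, -1.0, -2.0])
        bi = category_probabilities(
            np.array([theta_sub, theta_rs]),
            ItemParameters([a_sub, a_rs], intercepts),
            build_scoring_matrix("ers_mrs", 5, 1))
        two = category_probabilities(
            np.array([theta_sub, theta_rs, -theta_rs]),
            ItemParameters([a_sub, a_rs, a_rs], intercepts),
            build_scoring_matrix("ers_plus_mrs", 5, 1))
        np.testing.assert_allclose(bi, two, atol=1e-12)


def _gpcm_probabilities(theta, a, thresholds):
    """Independent generalized-partial-credit implementation, step form:
    P(k) ∝ exp(sum_{v<=k} a (theta - b_v))."""
    K = len(thresholds) + 1
    cum = np.zeros(K)
    for k in range(1, K):
        cum[k] = cum[k - 1] + a * (theta - thresholds[k - 1])
    p = np.exp(cum - cum.max())
    return p / p.sum()


@pytest.mark.parametrize("theta", [-2.0, -0.5, 0.0, 1.3, 2.7])
@pytest.mark.parametrize("a", [0.4, 1.0, 1.8])
def test_linear_scoring_reduces_to_gpcm(theta, a):
    """With the linear scoring row the model is the generalized partial
    credit model: category intercepts c_k map to step thresholds
    b_v = (c_{v-1} - c_v) / a."""
    intercepts = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
    thresholds = [(intercepts[v - 1] - intercepts[v]) / a for v in range(1, 5)]
    sm = build_scoring_matrix("null", 5, 1)
    ours = category_probabilities(np.array([theta]),
                                  ItemParameters([a], intercepts), sm)
    ref = _gpcm_probabilities(theta, a, thresholds)
    np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestProbabilityCurves:
    def test_single_point_matches_pointwise_probabilities(self):
        sm = build_scoring_matrix("null", 5, 1)
        item = ItemParameters([1.2], [-2, -1, 0, -1, -2])
        curves = probability_curves(item, sm, np.array([0.0]))
        np.testing.assert_allclose(
            curves[:, 0], category_probabilities(np.zeros(1), item, sm))

    def test_symmetric_item_columns_mirror(self):
        sm = build_scoring_matrix("null", 5, 1)
        item = ItemParameters([1.0], [-2, -1, 0, -1, -2])
        curves = probability_curves(item, sm, np.array([-1.0, 1.0]))
        np.testing.assert_allclose(curves[:, 0], curves[::-1, 1], atol=1e-12)

    def test_extreme_categories_grow_with_response_style(self):
        sm = build_scoring_matrix("ers_mrs", 5, 1)
        item = ItemParameters([1.0, 1.0], [-2, -1, 0, -1, -2])
        curves = probability_curves(item, sm, np.array([0.0, 3.0]),
                                    varied_dim=1)
        assert curves[0, 1] > curves[0, 0]
        assert curves[4, 1] > curves[4, 0]
        assert curves[2, 1] < curves[2, 0]

    def test_empty_grid_rejected(self):
        sm = build_scoring_matrix("null", 5, 1)
        item = ItemParameters([1.0], np.zeros(5))
        with pytest.raises(ValueError):
            probability_curves(item, sm, np.array([]))


@pytest.mark.parametrize("kind,n_sub,expected", [
    ("null", 1, 50),
    ("ers_mrs", 1, 61),
    ("ers_plus_mrs", 1, 73),
    ("ers_plus_mrs", 2, 76),
])
def test_free_parameter_counts_for_ten_items(kind, n_sub, expected):
    """J (1 + R + K - 1) slopes/intercepts plus T(T-1)/2 free correlations."""
    spec = ModelSpec.create(kind, 10, n_sub, 5)
    assert count_free_parameters(spec) == expected
    assert count_free_parameters(spec, 10) == expected
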