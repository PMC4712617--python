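"""Unit and property tests for the weighted error-rate primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erp import (
    LabeledSample,
    Weights,
    error_rate_down,
    error_rate_up,
    minimize_rule,
)
from erp.core import batch_minimized_error_rates

from conftest import grid_minimum_error

W1 = Weights(0.5, 0.5)
W2 = Weights(1 / 3, 2 / 3)


# random labelled samples with both groups present, n up to 8 per group
@st.composite
def labelled_samples(draw):
    n0 = draw(st.integers(1, 8))
    n1 = draw(st.integers(1, 8))
    values = draw(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
            min_size=n0 + n1,
            max_size=n0 + n1,
        )
    )
    labels = [0] * n0 + [1] * n1
    perm = draw(st.permutations(range(n0 + n1)))
    return LabeledSample(
        np.array(values)[list(perm)], np.array(labels)[list(perm)]
    )


@st.composite
def weight_pairs(draw):
    w0 = draw(st.floats(0.05, 0.95))
    return Weights(w0, 1.0 - w0)


# integer-valued samples: every inter-point gap is >= 1, so a 10,000-point
# grid over the data range is guaranteed to probe each threshold interval
@st.composite
def integer_valued_samples(draw):
    n0 = draw(st.integers(1, 4))
    n1 = draw(st.integers(1, 4))
    values = draw(
        st.lists(st.integers(-50, 50), min_size=n0 + n1, max_size=n0 + n1)
    )
    labels = [0] * n0 + [1] * n1
    perm = draw(st.permutations(range(n0 + n1)))
    return LabeledSample(
        np.array(values, dtype=float)[list(perm)], np.array(labels)[list(perm)]
    )


class TestPointwiseRates:
    @pytest.mark.parametrize(
        "values, labels, weights, c, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], W1, 2.5, 0.0),
            ([1, 2, 3, 4], [0, 0, 1, 1], W1, 5.0, 0.5),
            ([1, 3, 2, 4], [0, 1, 0, 1], W2, 1.5, 1 / 6),
        ],
    )
    def test_up_rule_examples(self, values, labels, weights, c, expected):
        sample = LabeledSample(values, labels)
        assert error_rate_up(sample, weights, c) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "values, labels, weights, c, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], W1, 2.5, 1.0),
            ([1, 2, 3, 4], [1, 1, 0, 0], W1, 2.5, 0.0),
            ([1, 3, 2, 4], [0, 1, 0, 1], W2, 1.5, 5 / 6),
        ],
    )
    def test_down_rule_examples(self, values, labels, weights, c, expected):
        sample = LabeledSample(values, labels)
        assert error_rate_down(sample, weights, c) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(labelled_samples(), weight_pairs(), st.floats(-1e6, 1e6))
    def test_complementarity(self, sample, weights, c):
        """Up and down error rates sum to one at every threshold."""
        total = error_rate_up(sample, weights, c) + error_rate_down(sample, weights, c)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestMinimization:
    @pytest.mark.parametrize(
        "values, labels, weights, mode, error, threshold, direction",
        [
            # separable upward shift
            ([1, 2, 3, 4], [0, 0, 1, 1], W1, "min", 0.0, 2.5, "up"),
            # downward shift: the up rule can do no better than a degenerate rule
            ([1, 2, 3, 4], [1, 1, 0, 0], W1, "up", 0.5, None, "up"),
            # oracle-derived: controls {1,2} vs experimentals {3,4} separate at 2.5
            ([1, 3, 2, 4], [0, 1, 0, 1], W2, "up", 0.0, 2.5, "up"),
        ],
    )
    def test_examples(self, values, labels, weights, mode, error, threshold, direction):
        result = minimize_rule(LabeledSample(values, labels), weights, mode)
        assert result.error_rate == pytest.approx(error, abs=1e-12)
        assert result.direction == direction
        if threshold is not None:
            assert result.threshold == pytest.approx(threshold)

    def test_all_values_identical(self):
        sample = LabeledSample([2.0, 2.0, 2.0], [0, 1, 1])
        result = minimize_rule(sample, W2, "min")
        assert result.error_rate == pytest.approx(W2.minimum)

    def test_tied_threshold_resolves_to_smallest(self):
        # both midpoints 1.5 and 3.5 achieve the same up-rule error
        sample = LabeledSample([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        result = minimize_rule(sample, W1, "up")
        assert result.threshold == pytest.approx(1.5)

    def test_equal_min_errors_tie_to_down(self):
        # symmetric arrangement: up and down minima coincide
        sample = LabeledSample([1.0, 2.0, 3.0, 4.0], [0, 1, 1, 0])
        er_up = minimize_rule(sample, W1, "up").error_rate
        er_down = minimize_rule(sample, W1, "down").error_rate
        assert er_up == er_down
        assert minimize_rule(sample, W1, "min").direction == "down"

    @settings(deadline=None, derandomize=True)
    @given(labelled_samples(), weight_pairs(), st.sampled_from(["up", "down", "min"]))
    def test_bound(self, sample, weights, mode):
        """The degenerate rules cap the minimised error at min(w0, w1)."""
        result = minimize_rule(sample, weights, mode)
        assert 0.0 <= result.error_rate <= weights.minimum + 1e-12

    @settings(deadline=None, derandomize=True)
    @given(integer_valued_samples(), weight_pairs(), st.sampled_from(["up", "down", "min"]))
    def test_grid_oracle_equivalence(self, sample, weights, mode):
        """Midpoint scan agrees with a dense 10,000-point threshold grid."""
        result = minimize_rule(sample, weights, mode)
        oracle = grid_minimum_error(sample.values, sample.labels, weights.w0, weights.w1, mode)
        assert result.error_rate == pytest.approx(oracle, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(labelled_samples(), weight_pairs())
    def test_label_swap_duality(self, sample, weights):
        """Swapping labels and weights maps the up minimum onto the down minimum."""
        swapped = LabeledSample(sample.values, 1 - sample.labels)
        dual = Weights(weights.w1, weights.w0)
        up = minimize_rule(sample, weights, "up")
        down = minimize_rule(swapped, dual, "down")
        assert up.error_rate == pytest.approx(down.error_rate, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        labelled_samples(),
        weight_pairs(),
        st.sampled_from(["up", "down", "min"]),
        st.sampled_from(["affine", "exp", "cube"]),
    )
    def test_monotone_invariance(self, sample, weights, mode, transform):
        """Strictly increasing transforms leave error rate and direction unchanged."""
        x = sample.values
        if transform == "affine":
            tx = 2.5 * x + 7.0
        elif transform == "exp":
            tx = np.exp(x / (1.0 + np.abs(x).max()))  # rescale to avoid overflow
        else:
            tx = x**3
        transformed = LabeledSample(tx, sample.labels)
        base = minimize_rule(sample, weights, mode)
        mapped = minimize_rule(transformed, weights, mode)
        assert mapped.error_rate == pytest.approx(base.error_rate, abs=1e-12)
        assert mapped.direction == base.direction

    def test_threshold_maps_through_transform_interval(self):
        """After a monotone transform the threshold separates the same subjects."""
        sample = LabeledSample([0.5, 1.1, 2.0, 7.3, 9.0], [0, 0, 1, 1, 1])
        transformed = LabeledSample(np.log(sample.values), sample.labels)
        base = minimize_rule(sample, W1, "up")
        mapped = minimize_rule(transformed, W1, "up")
        below_base = sample.values <= base.threshold
        below_mapped = transformed.values <= mapped.threshold
        assert np.array_equal(below_base, below_mapped)


class TestBatchPath:
    def test_matches_scalar_path(self, rng):
        labels = np.array([0] * 5 + [1] * 4)
        x = rng.random((50, 9))
        for mode in ("up", "down", "min"):
            batch = batch_minimized_error_rates(x, labels, W2, mode)
            scalar = [
                minimize_rule(LabeledSample(row, labels), W2, mode).error_rate
                for row in x
            ]
            np.testing.assert_allclose(batch, scalar, atol=1e-12)


class TestValidation:
    def test_bad_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Weights(0.5, 0.6)
        with pytest.raises(ValueError, match="positive"):
            Weights(0.0, 1.0)

    def test_weight_presets(self):
        assert Weights.from_preset(1) == Weights(0.5, 0.5)
        assert Weights.from_preset(2).w1 == pytest.approx(2 / 3)
        with pytest.raises(ValueError, match="preset"):
            Weights.from_preset(3)

    @pytest.mark.parametrize(
        "values, labels, match",
        [
            ([1.0, 2.0], [0, 0], "both groups"),
            ([1.0, np.inf], [0, 1], "finite"),
            ([1.0, 2.0], [0, 2], "labels"),
            ([1.0, 2.0, 3.0], [0, 1], "equal length"),
        ],
    )
    def test_bad_samples(self, values, labels, match):
        with pytest.raises(ValueError, match=match):
            LabeledSample(values, labels)

    def test_bad_mode(self, separable_sample):
        with pytest.raises(ValueError, match="mode"):
            minimize_rule(separable_sample, W1, "sideways")
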