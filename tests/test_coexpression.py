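"""Correlation metrics against slow scalar oracles, plus weight transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtofid import (
    ExpressionMatrix,
    bicor_matrix,
    soft_threshold,
    spearman_matrix,
    to_weights,
)


def _rank_then_pearson(x, y):
    """Brute-force Spearman oracle: average ranks by counting, then the
    textbook Pearson formula. Independent of scipy and the matrix path."""

    def avg_ranks(v):
        v = list(v)
        return [
            (sum(1 for u in v if u < w) + 1 + sum(1 for u in v if u <= w)) / 2.0
            for w in v
        ]

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def _bicor_oracle(x, y):
    """Scalar biweight midcorrelation, written from the definition."""

    def transform(v):
        v = np.asarray(v, float)
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        return (v - med) * w

    a, b = transform(x), transform(y)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _expr(rows):
    rows = np.asarray(rows, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(rows.shape[0])],
        [f"s{j}" for j in range(rows.shape[1])],
        rows,
    )


class TestSpearman:
    def test_monotone_pair_is_one(self):
        C = spearman_matrix(_expr([[1, 2, 3], [1, 4, 9]]))
        assert C.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_reversed_pair_is_minus_one(self):
        C = spearman_matrix(_expr([[1, 2, 3], [3, 2, 1]]))
        assert C.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_ties_use_average_ranks(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        C = spearman_matrix(_expr([x, y]))
        assert C.values[0, 1] == pytest.approx(_rank_then_pearson(x, y), abs=1e-12)

    def test_matches_oracle_on_random_profiles(self, rng):
        V = rng.normal(size=(6, 15))
        C = spearman_matrix(_expr(V))
        for i in range(6):
            for j in range(i + 1, 6):
                assert C.values[i, j] == pytest.approx(
                    _rank_then_pearson(V[i], V[j]), abs=1e-10
                )

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3])
    def test_invariant_under_monotone_row_transforms(self, rng, transform):
        V = rng.normal(size=(5, 20))
        base = spearman_matrix(_expr(V)).values
        V2 = V.copy()
        V2[2] = transform(V2[2])
        np.testing.assert_allclose(spearman_matrix(_expr(V2)).values, base, atol=1e-12)

    def test_constant_row_gives_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            C = spearman_matrix(_expr([[5, 5, 5, 5], [1, 2, 3, 4]]))
        assert C.values[0, 1] == 0.0
        assert C.values[0, 0] == 1.0
        assert "constant" in caplog.text


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=10)
        C = bicor_matrix(_expr([x, x + 0.0]))
        assert C.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negative_affine_is_minus_one(self, rng):
        x = rng.normal(size=12)
        C = bicor_matrix(_expr([x, -2.5 * x + 3.0]))
        assert C.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_outlier_pair_matches_scalar_oracle(self, rng):
        x = rng.normal(size=10)
        y = 0.8 * x + 0.2 * rng.normal(size=10)
        y[3] += 25.0  # gross outlier, down-weighted by the tricube-squared weights
        C = bicor_matrix(_expr([x, y]))
        assert C.values[0, 1] == pytest.approx(_bicor_oracle(x, y), abs=1e-12)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(C.values[0, 1]) > abs(pearson)  # robustness to the outlier

    def test_matches_oracle_on_random_matrix(self, rng):
        V = rng.normal(size=(5, 11))
        C = bicor_matrix(_expr(V))
        for i in range(5):
            for j in range(i + 1, 5):
                assert C.values[i, j] == pytest.approx(
                    _bicor_oracle(V[i], V[j]), abs=1e-12
                )

    def test_near_pearson_on_low_noise_linear_data(self, rng):
        x = np.linspace(0, 1, 30)
        y = x + 1e-3 * rng.normal(size=30)
        C = bicor_matrix(_expr([x, y]))
        assert C.values[0, 1] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-3)

    def test_zero_mad_falls_back_to_pearson(self, caplog):
        x = [1.0, 1.0, 1.0, 1.0, 5.0]  # MAD = 0
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        with caplog.at_level("WARNING"):
            C = bicor_matrix(_expr([x, y]))
        assert "zero MAD" in caplog.text
        # the zero-MAD row is Pearson-centred; the partner keeps bicor weights
        from wtofid.coexpression import bicor_pair

        assert C.values[0, 1] == pytest.approx(bicor_pair(x, y), abs=1e-12)


class TestWeights:
    def test_to_weights_takes_absolute_value_and_zeroes_diagonal(self):
        from wtofid import CorrelationMatrix

        C = CorrelationMatrix(
            ["a", "b"], np.array([[1.0, -0.7], [-0.7, 1.0]]), metric_tag="spearman"
        )
        W = to_weights(C)
        assert W.values[0, 1] == pytest.approx(0.7)
        assert W.values[0, 0] == 0.0 and W.values[1, 1] == 0.0
        assert W.values.min() >= 0.0 and W.values.max() <= 1.0

    def test_soft_threshold_arithmetic(self, rng):
        V = rng.normal(size=(4, 10))
        C = bicor_matrix(_expr(V))
        W6 = soft_threshold(C, beta=6.0)
        np.testing.assert_allclose(
            W6.values, to_weights(C).values ** 6.0, atol=1e-15
        )
        assert W6.soft_power == 6.0
        # direct arithmetic: 0.5^6
        assert 0.5**6 == pytest.approx(0.015625)

    def test_beta_one_is_identity_on_magnitudes(self, rng):
        V = rng.normal(size=(4, 10))
        C = spearman_matrix(_expr(V))
        W = soft_threshold(C, beta=1.0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(W.values[off], np.abs(C.values[off]), atol=1e-15)

    def test_beta_below_one_rejected(self, rng):
        C = spearman_matrix(_expr(rng.normal(size=(3, 5))))
        with pytest.raises(ValueError, match="beta"):
            soft_threshold(C, beta=0.5)

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=15, deadline=None)
    def test_produced_matrices_satisfy_range_invariants(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.normal(size=(6, 8))
        for C in (spearman_matrix(_expr(V)), bicor_matrix(_expr(V))):
            assert np.abs(C.values - C.values.T).max() <= 1e-12
            assert np.abs(C.values).max() <= 1.0
            np.testing.assert_allclose(np.diag(C.values), 1.0, atol=1e-12)
            W = soft_threshold(C, beta=6.0)
            assert W.values.min() >= 0.0 and W.values.max() <= 1.0
            assert np.all(np.diag(W.values) == 0.0)
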