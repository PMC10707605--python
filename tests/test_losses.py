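"""Entropy, mutual-information, MSE and KL objectives against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from helpers_naive import (
    naive_conditional_entropy,
    naive_entropy,
    naive_kl,
    naive_marginal_entropy,
    naive_mse,
)
from stainclust.losses import (
    LossWeights,
    affine_kl,
    conditional_entropy,
    entropy,
    marginal_entropy,
    mutual_information,
    reconstruction_mse,
    total_loss,
)

LN2 = math.log(2.0)


def random_stochastic(rng, n, k):
    p = rng.gamma(1.0, size=(n, k))
    return p / p.sum(axis=1, keepdims=True)


stochastic_matrices = st.integers(0, 10_000).map(
    lambda s: random_stochastic(np.random.default_rng(s), 1 + s % 40, 2 + s % 7)
)


class TestEntropy:
    def test_uniform_is_log_k(self):
        assert entropy(np.full(14, 1 / 14)) == pytest.approx(math.log(14), abs=1e-12)

    def test_one_hot_is_zero(self):
        assert entropy(np.array([0.0, 1.0, 0.0])) == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_summation(self):
        p = np.array([0.5, 0.25, 0.25])
        assert entropy(p) == pytest.approx(naive_entropy(p), abs=1e-12)
        assert entropy(p) == pytest.approx(1.0397, abs=1e-4)

    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            entropy(np.array([-0.1, 1.1]))
        with pytest.raises(ValueError):
            entropy(np.array([0.3, 0.3]))


class TestConditionalMarginal:
    def test_one_hot_rows_conditional_zero(self):
        p = np.eye(4)[[0, 1, 2, 3, 0]]
        assert conditional_entropy(p) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_rows_conditional_log_k(self):
        p = np.full((7, 4), 0.25)
        assert conditional_entropy(p) == pytest.approx(math.log(4), abs=1e-9)

    def test_conditional_hand_value(self):
        p = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert conditional_entropy(p) == pytest.approx(LN2 / 2, abs=1e-9)

    def test_marginal_degenerate_clustering(self):
        p = np.tile([1.0, 0.0, 0.0], (5, 1))
        assert marginal_entropy(p) == pytest.approx(0.0, abs=1e-9)

    def test_marginal_distinct_one_hots(self):
        p = np.eye(6)
        assert marginal_entropy(p) == pytest.approx(math.log(6), abs=1e-9)

    def test_marginal_column_mean_oracle(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert marginal_entropy(p) == pytest.approx(LN2, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            conditional_entropy(np.zeros((0, 3)))


class TestMutualInformation:
    def test_identical_rows_give_zero(self):
        p = np.tile([0.2, 0.3, 0.5], (9, 1))
        assert mutual_information(p) == pytest.approx(0.0, abs=1e-9)

    def test_perfect_diverse_assignment(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert mutual_information(p) == pytest.approx(LN2, abs=1e-12)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        p = random_stochastic(rng, 100, 5)
        expected = naive_marginal_entropy(p) - naive_conditional_entropy(p)
        assert mutual_information(p) == pytest.approx(expected, abs=1e-9)
        assert mutual_information(p) >= -1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(stochastic_matrices)
    def test_nonnegative_on_any_stochastic_matrix(self, p):
        assert mutual_information(p) >= -1e-10
        assert 0 <= conditional_entropy(p) <= math.log(p.shape[1]) + 1e-10
        assert 0 <= marginal_entropy(p) <= math.log(p.shape[1]) + 1e-10


class TestReconstructionMSE:
    def test_identical_inputs(self):
        x = np.random.default_rng(1).uniform(size=(3, 4))
        assert reconstruction_mse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros((2, 5))
        assert reconstruction_mse(x, x + 0.3) == pytest.approx(0.09, abs=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(size=(2, 6, 7))
        assert reconstruction_mse(a, b) == pytest.approx(naive_mse(a, b), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_mse(np.zeros(3), np.zeros(4))


class TestAffineKL:
    def test_identical_distributions(self):
        p = random_stochastic(np.random.default_rng(2), 10, 4)
        assert affine_kl(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_row(self):
        p = np.array([[1.0, 0.0]])
        q = np.array([[0.5, 0.5]])
        assert affine_kl(p, q) == pytest.approx(LN2, abs=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_gibbs_inequality_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_stochastic(rng, 6, 4)
        q = random_stochastic(rng, 6, 4)
        val = affine_kl(p, q)
        expected = np.mean([naive_kl(pi, qi) for pi, qi in zip(p, q)])
        assert val == pytest.approx(expected, rel=1e-7, abs=1e-9)
        assert val >= -1e-10


class TestTotalLoss:
    def test_all_zero_components(self):
        assert total_loss(0.0, 0.0, 0.0, 0.0).total == 0.0

    def test_hand_assembled_value(self):
        lb = total_loss(1.0, LN2, 0.0, 0.0)
        assert lb.total == pytest.approx(1 - 0.1 * LN2, abs=1e-12)
        assert lb.total == pytest.approx(0.9307, abs=1e-4)

    def test_default_weights(self):
        w = LossWeights()
        assert (w.lambda_me, w.lambda_ce, w.lambda_af) == (0.1, 0.03, 0.03)

    def test_breakdown_identity(self):
        w = LossWeights(0.2, 0.05, 0.07)
        lb = total_loss(0.4, 1.1, 0.6, 0.05, w)
        assert lb.total == pytest.approx(
            lb.recon
            - (w.lambda_me * lb.marginal_entropy - w.lambda_ce * lb.conditional_entropy)
            + w.lambda_af * lb.affine_kl,
            abs=1e-12,
        )

    def test_single_lambda_reduces_to_penalized_mi(self):
        """With equal entropy weights the objective is exactly
        (regularizer) - lambda * I(X;Y)."""
        lam = 0.25
        w = LossWeights(lam, lam, 0.5)
        recon, hy, hyx, af = 0.7, 1.2, 0.4, 0.1
        lb = total_loss(recon, hy, hyx, af, w)
        regularizer = recon + w.lambda_af * af
        assert lb.total == pytest.approx(regularizer - lam * (hy - hyx), abs=1e-12)

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            total_loss(-0.1, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            total_loss(0.1, 0.0, 0.0, -0.2)
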