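"""Objectives: hand-worked micro-batch values, mining vs exhaustive
search, invariants (nonnegativity, margin monotonicity, scale
invariance), and analytic-vs-numerical gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cchr import (
    LossConfig,
    binarize_joint,
    bit_balance_loss,
    contrastive_loss,
    cosine_similarity,
    mine_hard_negatives,
    quantization_loss,
    similarity,
    total_loss,
)
from cchr.objectives import cosine_matrix, total_loss_and_grads


class TestCosineAndSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0], [1, 0], 1.0),
            ([1, 0], [0, 1], 0.0),
            ([1, 1], [1, 0], 0.70710678),
            ([1, 2], [-1, -2], -1.0),
        ],
    )
    def test_cosine_hand_values(self, a, b, expected):
        assert cosine_similarity(np.array(a), np.array(b)) == pytest.approx(
            expected, abs=1e-8
        )

    def test_zero_vector_is_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    @pytest.mark.parametrize(
        "cos_pair,tau,expected",
        [
            (([1, 0], [0, 1]), 1.0, 1.0),          # exp(0)
            (([1, 0], [1, 0]), 1.0, 2.7182818),    # exp(1)
            (([1, 0], [-1, 0]), 0.5, 0.1353353),   # exp(-2)
        ],
    )
    def test_similarity_hand_values(self, cos_pair, tau, expected):
        a, b = cos_pair
        assert similarity(np.array(a), np.array(b), tau) == pytest.approx(
            expected, abs=1e-6
        )

    def test_similarity_rejects_bad_tau(self):
        with pytest.raises(ValueError, match="tau"):
            similarity(np.array([1.0]), np.array([1.0]), 0.0)

    def test_scale_invariance(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        assert cosine_similarity(3.7 * a, b) == pytest.approx(
            cosine_similarity(a, b), abs=1e-12
        )


class TestMining:
    def test_two_pairs_forced(self, rng):
        fv, fe = rng.standard_normal((2, 4)), rng.standard_normal((2, 4))
        m, n = mine_hard_negatives(fv, fe)
        assert m.tolist() == [1, 0] and n.tolist() == [1, 0]

    def test_three_pairs_known_argmax(self):
        # cos(Fv[0], Fe[1]) = 0.9 vs cos(Fv[0], Fe[2]) = 0.1
        fv = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        fe = np.array([[0.0, 1.0], [0.9, np.sqrt(1 - 0.81)], [0.1, np.sqrt(1 - 0.01)]])
        m, _ = mine_hard_negatives(fv, fe)
        assert m[0] == 1

    def test_all_identical_ties_to_smallest_index(self):
        fv = np.ones((4, 3))
        fe = np.ones((4, 3))
        m, n = mine_hard_negatives(fv, fe)
        assert m.tolist() == [1, 0, 0, 0]
        assert n.tolist() == [1, 0, 0, 0]

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mine_hard_negatives(np.ones((1, 3)), np.ones((1, 3)))

    def test_matches_exhaustive_search(self, rng):
        # oracle: O(Nb^2) loop over exp-cosine similarities
        for _ in range(100):
            nb = int(rng.integers(2, 33))
            fv = rng.standard_normal((nb, 8))
            fe = rng.standard_normal((nb, 8))
            m, n = mine_hard_negatives(fv, fe)
            c = cosine_matrix(fv, fe)
            s = np.exp(c)
            for k in range(nb):
                best_m = max(
                    (j for j in range(nb) if j != k), key=lambda j: (s[k, j], -j)
                )
                best_n = max(
                    (i for i in range(nb) if i != k), key=lambda i: (s[i, k], -i)
                )
                assert m[k] == best_m
                assert n[k] == best_n


class TestContrastiveLoss:
    def test_orthogonal_pairs_zero_loss(self):
        # aligned within pairs, orthogonal across: hinge = [0.25 - e + 1]_+ = 0
        fv = np.array([[1.0, 0.0], [0.0, 1.0]])
        fe = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert contrastive_loss(fv, fe, LossConfig()) == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_rows_give_margin(self):
        # S_pos = S_neg so each hinge is alpha; per-anchor sum 0.5, mean 0.5
        rows = np.ones((2, 4))
        assert contrastive_loss(rows, rows, LossConfig()) == pytest.approx(0.5, abs=1e-9)

    def test_zero_margin_identical_rows_zero(self):
        rows = np.ones((2, 4))
        cfg = LossConfig(margin_alpha=0.0)
        assert contrastive_loss(rows, rows, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_sum_reduction_scales_by_batch(self, rng):
        fv = rng.standard_normal((6, 4))
        fe = rng.standard_normal((6, 4))
        mean_val = contrastive_loss(fv, fe, LossConfig(reduction="mean"))
        sum_val = contrastive_loss(fv, fe, LossConfig(reduction="sum"))
        assert sum_val == pytest.approx(6 * mean_val, rel=1e-12)

    def test_margin_monotonicity(self, rng):
        fv = np.tanh(rng.standard_normal((8, 6)))
        fe = np.tanh(rng.standard_normal((8, 6)))
        losses = [
            contrastive_loss(fv, fe, LossConfig(margin_alpha=a))
            for a in (0.0, 0.1, 0.25, 0.5, 1.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_invariant_to_row_rescaling(self, rng):
        fv = rng.standard_normal((5, 4))
        fe = rng.standard_normal((5, 4))
        scales = rng.uniform(0.1, 10.0, size=(5, 1))
        cfg = LossConfig()
        assert contrastive_loss(fv * scales, fe, cfg) == pytest.approx(
            contrastive_loss(fv, fe, cfg), rel=1e-9
        )


class TestBinarizeAndQuantization:
    def test_sign_of_mean_hand_values(self):
        b = binarize_joint(np.array([[0.9, -0.2]]), np.array([[0.5, -0.8]]))
        assert b.tolist() == [[1.0, -1.0]]
        assert binarize_joint(np.array([[0.6]]), np.array([[-0.8]])).tolist() == [[-1.0]]

    def test_sign_zero_is_plus_one(self):
        b = binarize_joint(np.zeros((2, 3)), np.zeros((2, 3)))
        assert np.all(b == 1.0)

    def test_quantization_zero_at_exact_codes(self):
        b = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert quantization_loss(b, b, b) == 0.0

    @pytest.mark.parametrize(
        "fv,expected",
        [([[0.5, -0.5]], 1.0), ([[0.0, 0.0]], 4.0)],
    )
    def test_single_pair_hand_values(self, fv, expected):
        fv = np.array(fv)
        b = binarize_joint(fv, fv)
        assert quantization_loss(fv, fv, b) == pytest.approx(expected, abs=1e-12)


class TestBitBalance:
    def test_perfectly_balanced_is_zero(self):
        fv = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert bit_balance_loss(fv, fv) == 0.0

    def test_hand_values(self):
        fv = np.ones((2, 2))
        fe = np.zeros((2, 2))
        assert bit_balance_loss(fv, fe) == pytest.approx(4.0, abs=1e-12)
        assert bit_balance_loss(
            np.array([[1.0, -1.0]]), np.zeros((1, 2))
        ) == pytest.approx(2.0, abs=1e-12)

    def test_per_sample_mode_uses_row_sums(self):
        fv = np.array([[1.0, -1.0], [1.0, -1.0]])  # balanced rows, unbalanced cols
        assert bit_balance_loss(fv, fv, mode="per_sample_over_bits") == 0.0
        assert bit_balance_loss(fv, fv) == pytest.approx(8.0, abs=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="bit_balance_mode"):
            bit_balance_loss(np.ones((2, 2)), np.ones((2, 2)), mode="bogus")


class TestTotalLoss:
    def test_degenerate_weights_reduce_to_contrastive(self, rng):
        fv = np.tanh(rng.standard_normal((4, 8)))
        fe = np.tanh(rng.standard_normal((4, 8)))
        cfg = LossConfig(lambda1=0.0, lambda2=0.0)
        assert total_loss(fv, fe, cfg) == pytest.approx(
            contrastive_loss(fv, fe, cfg), rel=1e-12
        )

    def test_weighted_sum_of_known_components(self):
        # components (0.5, 1.0, 4.0) -> 0.5 + 0.001*1.0 + 0.01*4.0 = 0.541
        assert 0.5 + 0.001 * 1.0 + 0.01 * 4.0 == pytest.approx(0.541)
        # direct check on an actual batch: all rows identical so Lc = 0.5
        rows = np.ones((2, 4))
        cfg = LossConfig()
        expected = (
            contrastive_loss(rows, rows, cfg)
            + cfg.lambda1 * quantization_loss(rows, rows, binarize_joint(rows, rows))
            + cfg.lambda2 * bit_balance_loss(rows, rows)
        )
        assert total_loss(rows, rows, cfg) == pytest.approx(expected, rel=1e-12)

    @given(
        fv=arrays(np.float64, (5, 6), elements=st.floats(-0.99, 0.99)),
        fe=arrays(np.float64, (5, 6), elements=st.floats(-0.99, 0.99)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_all_losses_nonnegative(self, fv, fe):
        cfg = LossConfig()
        b = binarize_joint(fv, fe)
        assert contrastive_loss(fv, fe, cfg) >= 0.0
        assert quantization_loss(fv, fe, b) >= 0.0
        assert bit_balance_loss(fv, fe) >= 0.0
        assert total_loss(fv, fe, cfg) >= 0.0


class TestGradients:
    @pytest.mark.parametrize("reduction", ["mean", "sum"])
    def test_analytic_matches_finite_difference(self, rng, reduction):
        # B and the mining indices are step constants; for generic random
        # codes neither flips under a +-1e-6 perturbation
        nb, length = 6, 8
        fv = np.tanh(rng.standard_normal((nb, length)))
        fe = np.tanh(rng.standard_normal((nb, length)))
        cfg = LossConfig(reduction=reduction)
        b = binarize_joint(fv, fe)

        def frozen_total(fv_, fe_):
            return (
                contrastive_loss(fv_, fe_, cfg)
                + cfg.lambda1 * quantization_loss(fv_, fe_, b, reduction=reduction)
                + cfg.lambda2 * bit_balance_loss(fv_, fe_, reduction=reduction)
            )

        _, dfv, dfe = total_loss_and_grads(fv, fe, cfg)
        eps = 1e-6
        for target, grad in ((fv, dfv), (fe, dfe)):
            for _ in range(10):
                i = int(rng.integers(nb))
                j = int(rng.integers(length))
                orig = target[i, j]
                target[i, j] = orig + eps
                lp = frozen_total(fv, fe)
                target[i, j] = orig - eps
                lm = frozen_total(fv, fe)
                target[i, j] = orig
                num = (lp - lm) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-9)
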