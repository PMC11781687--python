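"""Encoder, discriminators and the three loss terms against hand oracles."""

import numpy as np
import pytest

from asgcl import (EncoderConfig, LossWeights, bilinear_discriminator,
                   cosine_discriminator, encode, graph_contrastive_loss,
                   node_contrastive_loss, pair_scores, propagate_layer,
                   readout_summary, supervised_loss, total_loss)
from asgcl._tensor import Tensor


def _leaky(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


class TestPropagateLayer:
    def test_empty_adjacency_is_pointwise(self, rng):
        X = rng.standard_normal((4, 3))
        W = rng.standard_normal((3, 2))
        out = propagate_layer(X, np.zeros((4, 4)), W)
        # self-loops only: A_hat = I, so act(X W)
        np.testing.assert_allclose(out, _leaky(X @ W))

    def test_automorphic_nodes_get_equal_rows(self, rng):
        # path a-b, c-d with equal features on (a, c) and (b, d)
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        X = rng.standard_normal((2, 3))[[0, 1, 0, 1]]
        W = rng.standard_normal((3, 2))
        out = propagate_layer(X, A, W)
        np.testing.assert_allclose(out[0], out[2])
        np.testing.assert_allclose(out[1], out[3])

    def test_matches_nested_loop_oracle(self, rng):
        X = rng.standard_normal((4, 3))
        W = rng.standard_normal((3, 2))
        A = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0]],
                     dtype=float)
        A_tilde = A + np.eye(4)
        deg = A_tilde.sum(1)
        pre = np.zeros((4, 2))
        for i in range(4):
            for j in range(4):
                for k in range(3):
                    for l in range(2):
                        pre[i, l] += (A_tilde[i, j] /
                                      np.sqrt(deg[i] * deg[j])) * X[j, k] * W[k, l]
        np.testing.assert_allclose(propagate_layer(X, A, W), _leaky(pre))


class TestEncode:
    def test_k1_equals_single_layer(self, rng):
        X = rng.standard_normal((5, 3))
        A = (rng.random((5, 5)) < 0.5).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        W = rng.standard_normal((3, 2))
        np.testing.assert_allclose(encode(X, A, [W]), propagate_layer(X, A, W))

    def test_deterministic(self, rng):
        X = rng.standard_normal((5, 3))
        A = np.eye(5)[::-1] + np.eye(5)
        np.fill_diagonal(A, 0)
        W = rng.standard_normal((3, 2))
        np.testing.assert_array_equal(encode(X, A, [W]), encode(X, A, [W]))

    def test_k2_is_composition(self, rng):
        X = rng.standard_normal((5, 3))
        A = (rng.random((5, 5)) < 0.5).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        W1 = rng.standard_normal((3, 4))
        W2 = rng.standard_normal((4, 2))
        manual = propagate_layer(propagate_layer(X, A, W1), A, W2)
        np.testing.assert_allclose(encode(X, A, [W1, W2]), manual)

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((5, 3))
        A = (rng.random((5, 5)) < 0.5).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        W = rng.standard_normal((3, 2))
        perm = rng.permutation(5)
        out = encode(X, A, [W])
        out_p = encode(X[perm], A[np.ix_(perm, perm)], [W])
        np.testing.assert_allclose(out_p, out[perm])


class TestCosineDiscriminator:
    def test_identical_vectors(self):
        assert cosine_discriminator(np.array([1.0, 2.0]),
                                    np.array([1.0, 2.0])) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_discriminator(np.array([1.0, 0.0]),
                                    np.array([0.0, 3.0])) == pytest.approx(0.0)

    def test_matches_explicit_arithmetic(self, rng):
        u, v = rng.standard_normal(5), rng.standard_normal(5)
        num = sum(u[i] * v[i] for i in range(5))
        den = np.sqrt(sum(x * x for x in u)) * np.sqrt(sum(x * x for x in v))
        assert cosine_discriminator(u, v) == pytest.approx(num / den)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            cosine_discriminator(np.zeros(3), np.ones(3))


class TestNodeContrastiveLoss:
    def test_hand_computed_two_node_case(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss = node_contrastive_loss(Z, Z, tau=1.0)
        # per anchor: log(e / (e + 2)); loss is the negation
        assert loss == pytest.approx(-np.log(np.e / (np.e + 2)), abs=1e-4)

    def test_identical_views_large_tau_limit(self, rng):
        N = 6
        Z = rng.standard_normal((N, 4))
        loss = node_contrastive_loss(Z, Z, tau=1e6)
        # all similarities ~equal: softmax is uniform over 2N-1 candidates
        assert loss == pytest.approx(np.log(2 * N - 1), abs=1e-3)

    def test_permutation_invariance(self, rng):
        Zu, Zv = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        perm = rng.permutation(5)
        a = node_contrastive_loss(Zu, Zv, tau=0.5)
        b = node_contrastive_loss(Zu[perm], Zv[perm], tau=0.5)
        assert a == pytest.approx(b)

    def test_single_node_raises(self):
        with pytest.raises(ValueError):
            node_contrastive_loss(np.ones((1, 3)), np.ones((1, 3)))

    def test_decreases_when_positive_alignment_improves(self, rng):
        Zu = rng.standard_normal((6, 4))
        Zv = rng.standard_normal((6, 4))
        base = node_contrastive_loss(Zu, Zv, tau=0.5)
        better = node_contrastive_loss(Zu, 0.5 * Zv + 0.5 * Zu, tau=0.5)
        assert better < base


class TestGraphLevel:
    def test_readout_of_zeros_is_half(self):
        np.testing.assert_allclose(readout_summary(np.zeros((4, 3))), 0.5)

    def test_readout_permutation_invariant(self, rng):
        H = rng.standard_normal((5, 3))
        np.testing.assert_allclose(readout_summary(H),
                                   readout_summary(H[rng.permutation(5)]))

    def test_readout_matches_explicit_loop(self, rng):
        H = rng.standard_normal((4, 3))
        mean = np.array([sum(H[i, j] for i in range(4)) / 4 for j in range(3)])
        np.testing.assert_allclose(readout_summary(H), 1 / (1 + np.exp(-mean)))

    def test_bilinear_zero_embedding_is_half(self, rng):
        V = rng.standard_normal(3)
        assert bilinear_discriminator(np.zeros(3), V, np.eye(3)) == \
            pytest.approx(0.5)

    def test_bilinear_identity_alignment_saturates(self):
        V = np.full(3, 10.0)
        assert bilinear_discriminator(V, V, np.eye(3)) > 0.999

    def test_bilinear_matches_explicit_loop(self, rng):
        h, V = rng.standard_normal(4), rng.standard_normal(4)
        W = rng.standard_normal((4, 4))
        raw = sum(h[i] * W[i, j] * V[j] for i in range(4) for j in range(4))
        assert bilinear_discriminator(h, V, W) == \
            pytest.approx(1 / (1 + np.exp(-raw)))

    def test_all_half_outputs_give_two_log_two(self, rng):
        N = 5
        H_pos = rng.standard_normal((N, 3))
        H_neg = rng.standard_normal((N, 3))
        V, U = rng.standard_normal(3), rng.standard_normal(3)
        # W_V = 0 forces every discriminator output to exactly 0.5
        loss = graph_contrastive_loss(H_pos, H_neg, V, U, np.zeros((3, 3)))
        assert loss == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_perfect_discrimination_drives_loss_to_zero(self):
        H_pos = np.full((3, 2), 50.0)
        H_neg = -H_pos
        V = np.full(2, 1.0)
        U = np.full(2, -1.0)
        loss = graph_contrastive_loss(H_pos, H_neg, V, U, np.eye(2))
        assert loss < 1e-3

    def test_matches_explicit_double_sum(self, rng):
        N = 6
        H_pos = rng.standard_normal((N, 3))
        H_neg = rng.standard_normal((N, 3))
        V, U = rng.standard_normal(3), rng.standard_normal(3)
        W = rng.standard_normal((3, 3))

        def phi(h, s):
            return 1 / (1 + np.exp(-(h @ W @ s)))

        f1 = sum(np.log(phi(H_pos[i], V)) for i in range(N)) + \
            sum(np.log(1 - phi(H_neg[i], V)) for i in range(N))
        f2 = sum(np.log(phi(H_neg[i], U)) for i in range(N)) + \
            sum(np.log(1 - phi(H_pos[i], U)) for i in range(N))
        expected = -(f1 + f2) / (2 * N)
        assert graph_contrastive_loss(H_pos, H_neg, V, U, W) == \
            pytest.approx(expected, abs=1e-9)

    def test_invariant_under_joint_node_permutation(self, rng):
        N = 5
        H_pos = rng.standard_normal((N, 3))
        H_neg = rng.standard_normal((N, 3))
        V, U = rng.standard_normal(3), rng.standard_normal(3)
        W = rng.standard_normal((3, 3))
        perm = rng.permutation(N)
        a = graph_contrastive_loss(H_pos, H_neg, V, U, W)
        b = graph_contrastive_loss(H_pos[perm], H_neg[perm], V, U, W)
        assert a == pytest.approx(b)


class TestPairScores:
    def test_orthogonal_embeddings_score_half(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = pair_scores(H, [(0, 0)], m=1, n=1)
        assert s[0] == pytest.approx(0.5)

    def test_matched_embeddings_sigmoid_of_norm(self):
        h = np.full(5, np.sqrt(2.0))  # squared norm 10
        H = np.stack([h, h])
        s = pair_scores(H, [(0, 0)], m=1, n=1)
        assert s[0] == pytest.approx(1 / (1 + np.exp(-10.0)))

    def test_symmetric_in_the_two_vectors(self, rng):
        a, b = rng.standard_normal(4), rng.standard_normal(4)
        s1 = pair_scores(np.stack([a, b]), [(0, 0)], m=1, n=1)
        s2 = pair_scores(np.stack([b, a]), [(0, 0)], m=1, n=1)
        assert s1[0] == pytest.approx(s2[0])

    def test_partition_violation_raises(self, rng):
        H = rng.standard_normal((4, 3))
        with pytest.raises(ValueError):
            pair_scores(H, [(2, 0)], m=2, n=2)
        with pytest.raises(ValueError):
            pair_scores(H, [(0, 5)], m=2, n=2)


class TestSupervisedAndTotal:
    def test_perfect_predictions_near_zero(self):
        p = np.array([1.0, 0.0, 1.0])
        y = np.array([1.0, 0.0, 1.0])
        assert supervised_loss(p, y) <= 1e-6

    def test_uniform_predictions_log_two(self):
        p = np.full(8, 0.5)
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        assert supervised_loss(p, y) == pytest.approx(np.log(2))

    def test_matches_per_element_loop(self, rng):
        p = rng.uniform(0.05, 0.95, 10)
        y = (rng.random(10) < 0.5).astype(float)
        expected = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                             for pi, yi in zip(p, y)])
        assert supervised_loss(p, y) == pytest.approx(expected)

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            supervised_loss(np.array([]), np.array([]))

    def test_total_loss_weighting(self):
        assert total_loss(3.0, 5.0, 7.0, LossWeights(1.0, 0.0, 0.0)) == 3.0
        assert total_loss(1.0, 1.0, 1.0, LossWeights()) == pytest.approx(1.0)
        a = total_loss(1.0, 2.0, 3.0, LossWeights())
        b = total_loss(2.0, 4.0, 6.0, LossWeights())
        assert b == pytest.approx(2 * a)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            LossWeights(-0.2, 1.0, 0.2)


def test_losses_finite_and_nonnegative_on_random_inputs(rng):
    for _ in range(10):
        N = int(rng.integers(3, 8))
        Zu = rng.standard_normal((N, 4)) * rng.uniform(0.1, 10)
        Zv = rng.standard_normal((N, 4)) * rng.uniform(0.1, 10)
        l1 = node_contrastive_loss(Zu, Zv, tau=0.5)
        W = rng.standard_normal((4, 4)) * 5
        l2 = graph_contrastive_loss(Zu, Zv, rng.standard_normal(4),
                                    rng.standard_normal(4), W)
        l3 = supervised_loss(rng.uniform(0, 1, N), (rng.random(N) < 0.5))
        for l in (l1, l2, l3):
            assert np.isfinite(l) and l >= 0


def test_gradients_flow_through_all_losses(rng):
    """The combined objective must backpropagate to the embeddings."""
    Z = Tensor(rng.standard_normal((4, 3)), requires_grad=True)
    W = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
    l_nod = node_contrastive_loss(Z, Z * 0.9, tau=0.5)
    V = readout_summary(Z)
    l_gra = graph_contrastive_loss(Z, Z * -1.0, V, V * 0.5, W)
    p = pair_scores(Z, [(0, 0), (1, 1)], m=2, n=2)
    l_sup = supervised_loss(p, np.array([1.0, 0.0]))
    total = total_loss(l_sup, l_nod, l_gra, LossWeights())
    total.backward()
    assert Z.grad is not None and np.isfinite(Z.grad).all()
    assert W.grad is not None and np.isfinite(W.grad).all()
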