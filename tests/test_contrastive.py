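"""Contrastive losses against scalar brute-force oracles; momentum and KNN contracts."""

import math

import numpy as np
import pytest

from scdistill.contrastive import (
    ContrastiveConfig,
    build_knn,
    contrastive_step_loss,
    hybrid_info_nce,
    info_nce,
    momentum_update,
    train_contrastive,
)
from scdistill.nnet import MLP


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def info_nce_bruteforce(q, k_pos, k_negs, tau):
    num = math.exp(float(np.dot(q, k_pos)) / tau)
    den = num + sum(math.exp(float(np.dot(q, kn)) / tau) for kn in k_negs)
    return -math.log(num / den)


def hybrid_bruteforce(q, k_i, k_ic_list, k_negs, lam, tau, printed=False):
    s_ic = float(np.mean([np.dot(q, k) for k in k_ic_list]))
    num = math.exp((1 - lam) * float(np.dot(q, k_i)) / tau) + math.exp(lam * s_ic / tau)
    den = sum(math.exp(float(np.dot(q, kn)) / tau) for kn in k_negs)
    if not printed:
        den += num
    return -math.log(num / den)


class TestInfoNce:
    def test_closed_form_aligned_positive_orthogonal_negatives(self):
        for M in (1, 8, 64):
            q = np.zeros(M + 1)
            q[0] = 1.0
            negs = np.eye(M + 1)[1:]
            loss = info_nce(q, q, negs, tau=1.0)
            assert loss == pytest.approx(-math.log(math.e / (math.e + M)), abs=1e-12)

    def test_no_negatives_gives_zero(self):
        q = _unit([1.0, 2.0])
        assert info_nce(q, q, np.empty((0, 2)), tau=0.5) == 0.0

    def test_monotone_in_positive_similarity(self, rng):
        negs = _unit(rng.normal(size=(6, 4)))
        q = _unit(rng.normal(size=4))
        losses = []
        for a in (0.1, 0.5, 0.9):
            k = _unit(a * q + (1 - a) * _unit(rng.normal(size=4)))
            # construct positives of increasing alignment with q
            losses.append(info_nce(q, _unit(q * a + negs[0] * (1 - a)), negs, 0.2))
        assert losses[0] > losses[-1]

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            info_nce(np.zeros(3), np.ones(3), np.ones((1, 3)), 1.0)

    def test_matches_bruteforce_random(self, rng):
        for _ in range(100):
            q = _unit(rng.normal(size=4))
            k = _unit(rng.normal(size=4))
            negs = _unit(rng.normal(size=(5, 4)))
            mine = info_nce(q, k, negs, tau=0.3)
            assert mine == pytest.approx(info_nce_bruteforce(q, k, negs, 0.3), abs=1e-8)


class TestHybridInfoNce:
    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("printed", [False, True])
    def test_matches_bruteforce_random(self, rng, lam, printed):
        cfg = ContrastiveConfig(tau=0.25, lambda_mix=lam, printed_denominator=printed)
        for _ in range(100):
            q = _unit(rng.normal(size=4))
            k_i = _unit(rng.normal(size=4))
            k_ic = _unit(rng.normal(size=(3, 4)))
            negs = _unit(rng.normal(size=(7, 4)))
            mine = hybrid_info_nce(q, k_i, k_ic, negs, cfg)
            expect = hybrid_bruteforce(q, k_i, list(k_ic), list(negs), lam, 0.25, printed)
            assert mine == pytest.approx(expect, abs=1e-8)

    def test_equal_positives_at_half_lambda(self, rng):
        cfg = ContrastiveConfig(tau=0.2, lambda_mix=0.5)
        q = _unit(rng.normal(size=4))
        k = _unit(rng.normal(size=4))
        negs = _unit(rng.normal(size=(4, 4)))
        mine = hybrid_info_nce(q, k, k[None, :], negs, cfg)
        expect = hybrid_bruteforce(q, k, [k], list(negs), 0.5, 0.2)
        assert mine == pytest.approx(expect, abs=1e-10)

    def test_default_denominator_is_nonnegative(self, rng):
        cfg = ContrastiveConfig()
        for _ in range(50):
            loss = hybrid_info_nce(
                _unit(rng.normal(size=4)), _unit(rng.normal(size=4)),
                _unit(rng.normal(size=(2, 4))), _unit(rng.normal(size=(5, 4))), cfg
            )
            assert loss >= 0.0

    def test_empty_neighbours_falls_back(self, rng):
        cfg = ContrastiveConfig(tau=1.0)
        q = _unit(rng.normal(size=4))
        k = _unit(rng.normal(size=4))
        negs = _unit(rng.normal(size=(3, 4)))
        with pytest.warns(UserWarning, match="empty neighbour"):
            loss = hybrid_info_nce(q, k, np.empty((0, 4)), negs, cfg)
        assert loss == pytest.approx(info_nce(q, k, negs, 1.0), abs=1e-12)


class TestStepLoss:
    def test_alpha_zero_equals_hybrid(self, rng):
        cfg = ContrastiveConfig(alpha_l1=0.0)
        q = _unit(rng.normal(size=4))
        args = (q, _unit(rng.normal(size=4)), _unit(rng.normal(size=(2, 4))),
                _unit(rng.normal(size=(5, 4))))
        assert contrastive_step_loss(*args, cfg) == pytest.approx(
            hybrid_info_nce(*args, cfg), abs=1e-12
        )

    def test_l1_additivity_on_raw_query(self, rng):
        base = ContrastiveConfig(alpha_l1=0.0)
        pen = ContrastiveConfig(alpha_l1=0.01)
        q_raw = rng.normal(size=4) * 3.0
        q = _unit(q_raw)
        args = (q, _unit(rng.normal(size=4)), _unit(rng.normal(size=(2, 4))),
                _unit(rng.normal(size=(5, 4))))
        delta = contrastive_step_loss(*args, pen, q_raw=q_raw) - contrastive_step_loss(
            *args, base, q_raw=q_raw
        )
        assert delta == pytest.approx(0.01 * np.abs(q_raw).sum(), abs=1e-10)


class TestMomentum:
    def _state(self, rng, m):
        from scdistill.contrastive import DynamicEncoderState

        enc = MLP([4, 3], rng)
        return DynamicEncoderState(
            query_encoder=enc, key_encoder=MLP([4, 3], rng),
            query_head=None, key_head=None, momentum_m=m,
        )

    def test_m_one_freezes_key(self, rng):
        st = self._state(rng, 1.0)
        before = st.key_encoder.get_weights()
        momentum_update(st)
        for a, b in zip(before, st.key_encoder.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_m_zero_copies_query(self, rng):
        st = self._state(rng, 0.0)
        momentum_update(st)
        for a, b in zip(st.query_encoder.get_weights(), st.key_encoder.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_geometric_convergence_to_query(self, rng):
        m = 0.9
        st = self._state(rng, m)
        gap0 = sum(
            np.abs(a - b).sum()
            for a, b in zip(st.query_encoder.get_weights(), st.key_encoder.get_weights())
        )
        for it in range(100):
            momentum_update(st)
        gap = sum(
            np.abs(a - b).sum()
            for a, b in zip(st.query_encoder.get_weights(), st.key_encoder.get_weights())
        )
        assert gap == pytest.approx(gap0 * m ** 100, rel=1e-6)

    def test_scalar_convex_combination(self, rng):
        st = self._state(rng, 0.9)
        st.key_encoder.set_weights([np.zeros_like(w) for w in st.key_encoder.get_weights()])
        st.query_encoder.set_weights([np.ones_like(w) for w in st.query_encoder.get_weights()])
        momentum_update(st)
        for w in st.key_encoder.get_weights():
            np.testing.assert_allclose(w, 0.1, atol=1e-7)


class TestBuildKnn:
    def test_collinear_nearest_endpoint(self):
        X = np.array([[0.0], [1.0], [3.0]])
        idx = build_knn(X, 1)
        assert idx.neighbor_ids[1, 0] == 0  # middle point's 1-NN is nearer endpoint

    def test_self_excluded(self, rng):
        X = rng.normal(size=(30, 5))
        idx = build_knn(X, 4)
        assert not np.any(idx.neighbor_ids == np.arange(30)[:, None])

    def test_duplicate_is_nearest_at_zero_distance(self, rng):
        X = rng.normal(size=(10, 3))
        X[7] = X[2]
        idx = build_knn(X, 1)
        assert idx.neighbor_ids[2, 0] == 7
        assert idx.distances[2, 0] == 0.0

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            build_knn(rng.normal(size=(5, 2)), 5)


class TestTrainContrastive:
    def test_smoke_and_determinism(self, tiny_processed):
        expr, _ = tiny_processed
        cfg = ContrastiveConfig(epochs=2, batch_size=64, queue_size=128, seed=3)
        Z1, st1 = train_contrastive(expr.values, cfg, layer_sizes=[32], bottleneck_dim=8)
        Z2, _ = train_contrastive(expr.values, cfg, layer_sizes=[32], bottleneck_dim=8)
        assert np.all(np.isfinite(Z1))
        np.testing.assert_array_equal(Z1, Z2)

    def test_separates_clusters(self, tiny_processed, tiny_counts):
        expr, raw = tiny_processed
        cfg = ContrastiveConfig(epochs=20, batch_size=64, queue_size=128, seed=0)
        Z, _ = train_contrastive(expr.values, cfg, layer_sizes=[64, 32], bottleneck_dim=8)
        y = np.asarray(raw.labels)
        U = Z / np.linalg.norm(Z, axis=1, keepdims=True)
        S = U @ U.T
        same = y[:, None] == y[None, :]
        np.fill_diagonal(same, False)
        off = ~np.eye(len(y), dtype=bool)
        within = S[same].mean()
        between = S[off & ~same].mean()
        assert within > between

    def test_queue_smaller_than_batch_rejected(self, tiny_processed):
        expr, _ = tiny_processed
        cfg = ContrastiveConfig(epochs=1, batch_size=64, queue_size=32)
        with pytest.raises(ValueError, match="queue_size"):
            train_contrastive(expr.values, cfg, layer_sizes=[16], bottleneck_dim=4)


def test_knn_refresh_runs_and_differs_from_static(tiny_processed):
    expr, _ = tiny_processed
    base = ContrastiveConfig(epochs=6, batch_size=64, queue_size=128, seed=1)
    refreshed = ContrastiveConfig(epochs=6, batch_size=64, queue_size=128, seed=1,
                                  refresh_knn_every=2)
    Z_static, _ = train_contrastive(expr.values, base, layer_sizes=[32], bottleneck_dim=8)
    Z_refresh, _ = train_contrastive(expr.values, refreshed, layer_sizes=[32], bottleneck_dim=8)
    assert np.all(np.isfinite(Z_refresh))
    assert not np.array_equal(Z_static, Z_refresh)
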