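"""ZINB likelihood against scipy oracles, DEC algebra, and training contracts."""

import numpy as np
import pytest
from scipy import stats

from scdistill.io_preprocess import preprocess
from scdistill.synthetic_data import SimConfig, simulate_counts
from scdistill.zinb_autoencoder import (
    EncoderConfig,
    SoftAssignment,
    ZINBAutoencoder,
    ZINBParams,
    clustering_kl,
    corrupt,
    soft_assign,
    target_distribution,
    zinb_nll,
)


def _params(mu, theta, pi, shape):
    full = lambda v: np.full(shape, v, dtype=float)
    return ZINBParams(mu=full(mu), theta=full(theta), pi=full(pi))


def zinb_logpmf_oracle(x, mu, theta, pi):
    """Independent route: scipy's negative binomial pmf plus the zero mixture."""
    p = theta / (theta + mu)
    nb = stats.nbinom.pmf(x, theta, p)
    return np.log(pi * (x == 0) + (1 - pi) * nb)


class TestZinbNll:
    def test_pure_dropout_zero_has_likelihood_one(self):
        nll = zinb_nll(np.zeros((2, 2)), _params(1.0, 1.0, 1.0, (2, 2)))
        assert nll == pytest.approx(0.0, abs=1e-12)

    def test_nb_zero_hand_value(self):
        # pi=0, x=0, mu=theta=1: pmf = (1/2)^1 -> NLL = log 2
        nll = zinb_nll(np.zeros((1, 1)), _params(1.0, 1.0, 0.0, (1, 1)))
        assert nll == pytest.approx(np.log(2.0), abs=1e-12)

    def test_poisson_limit_at_large_dispersion(self):
        x = np.arange(11.0).reshape(1, -1)
        nll = zinb_nll(x, _params(2.0, 1e6, 0.0, x.shape), reduce="none")
        poisson = -stats.poisson.logpmf(x, 2.0)
        np.testing.assert_allclose(nll, poisson, atol=1e-3)

    @pytest.mark.parametrize("mu", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("theta", [0.5, 2.0, 100.0])
    @pytest.mark.parametrize("pi", [0.0, 0.3, 0.9])
    def test_matches_scipy_oracle_on_grid(self, mu, theta, pi):
        x = np.arange(51.0)
        mine = zinb_nll(x, _params(mu, theta, pi, x.shape), reduce="none")
        oracle = -zinb_logpmf_oracle(x, mu, theta, pi)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)

    @pytest.mark.parametrize("mu,theta", [(0.5, 0.5), (2.0, 2.0), (10.0, 100.0)])
    def test_pmf_sums_to_one(self, mu, theta):
        x = np.arange(10001.0)
        for pi in (0.0, 0.3, 0.9):
            nll = zinb_nll(x, _params(mu, theta, pi, x.shape), reduce="none")
            assert np.exp(-nll).sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            zinb_nll(np.array([-1.0]), _params(1, 1, 0, (1,)))
        with pytest.raises(ValueError):
            zinb_nll(np.array([1.5]), _params(1, 1, 0, (1,)))


class TestZinbParamsInvariants:
    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            ZINBParams(mu=np.array([-1.0]), theta=np.array([1.0]), pi=np.array([0.5]))
        with pytest.raises(ValueError):
            ZINBParams(mu=np.array([1.0]), theta=np.array([1.0]), pi=np.array([1.5]))
        with pytest.raises(ValueError):
            ZINBParams(mu=np.array([[1.0]]), theta=np.array([1.0, 2.0]), pi=np.array([0.5]))


class TestCorrupt:
    def test_sigma_zero_is_identity(self, rng):
        X = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(corrupt(X, 0.0, seed=1), X)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(corrupt(X, 1.0, seed=9), corrupt(X, 1.0, seed=9))

    def test_gaussian_moments(self):
        out = corrupt(np.zeros(100_000), 1.0, seed=3)
        assert abs(out.mean()) < 3 / np.sqrt(100_000)
        assert abs(out.var() - 1.0) < 3 * np.sqrt(2 / 100_000)


class TestDecAlgebra:
    def test_single_cluster_assignment_is_one(self, rng):
        Z = rng.normal(size=(10, 3))
        sa = soft_assign(Z, Z.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(sa.Q, 1.0)

    def test_two_center_hand_value(self):
        d = 3.0
        sa = soft_assign(np.array([[0.0, 0.0]]), np.array([[0.0, 0.0], [d, 0.0]]))
        expected_q1 = 1.0 / (1.0 + 1.0 / (1.0 + d * d))
        assert sa.Q[0, 0] == pytest.approx(expected_q1, abs=1e-12)

    def test_target_is_identity_on_one_hot(self):
        Q = np.eye(4)[[0, 1, 2, 3, 0]]
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_target_uniform_fixed_point(self):
        Q = np.full((6, 2), 0.5)
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_kl_identity_and_hand_value(self):
        P = np.array([[1.0, 0.0]])
        Q = np.array([[0.5, 0.5]])
        assert clustering_kl(P, P) == pytest.approx(0.0, abs=1e-12)
        assert clustering_kl(P, Q) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_random_instances_properties(self, rng):
        # soft_assign rows sum to 1; KL non-negative; identity on one-hot
        for _ in range(200):
            Z = rng.normal(size=(12, 4))
            C = rng.normal(size=(5, 4))
            sa = soft_assign(Z, C)
            np.testing.assert_allclose(sa.Q.sum(axis=1), 1.0, atol=1e-9)
            P = target_distribution(sa.Q)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert clustering_kl(P, sa.Q) >= 0.0
            one_hot = np.eye(5)[rng.integers(0, 5, size=8)]
            np.testing.assert_allclose(target_distribution(one_hot), one_hot, atol=1e-12)

    def test_target_sharpens_under_equal_frequencies(self, rng):
        # with equal soft cluster frequencies p ∝ q², so the per-row max can
        # only grow; the frequency-normalised target does NOT guarantee this
        # for unbalanced clusters (the 1/f_j reweighting is meant to shift
        # mass toward rarer clusters)
        for _ in range(200):
            row = rng.dirichlet(np.ones(5))
            Q = np.stack([np.roll(row, k) for k in range(5)])  # equal column sums
            P = target_distribution(Q)
            assert np.all(P.max(axis=1) >= Q.max(axis=1) - 1e-12)


@pytest.fixture(scope="module")
def small_model(tiny_processed):
    expr, raw = tiny_processed
    cfg = EncoderConfig(layer_sizes=[64, 32], bottleneck_dim=8, n_clusters=3,
                        batch_size=64)
    model = ZINBAutoencoder(expr.values.shape[1], cfg, seed=0)
    model.pretrain(expr, raw, epochs=2, seed=0)
    return model


class TestTraining:
    def test_pretrain_smoke_and_loss_finite(self, small_model):
        assert np.isfinite(small_model.loss_log[-1]["loss"])

    def test_more_epochs_reduce_loss(self, tiny_processed):
        expr, raw = tiny_processed
        cfg = EncoderConfig(layer_sizes=[64, 32], bottleneck_dim=8, n_clusters=3,
                            batch_size=64)
        m1 = ZINBAutoencoder(expr.values.shape[1], cfg, seed=0)
        l_short = m1.pretrain(expr, raw, epochs=1, seed=0)
        m2 = ZINBAutoencoder(expr.values.shape[1], cfg, seed=0)
        l_long = m2.pretrain(expr, raw, epochs=25, seed=0)
        assert l_long < l_short

    def test_pretrain_seed_reproducible(self, tiny_processed):
        expr, raw = tiny_processed
        cfg = EncoderConfig(layer_sizes=[32], bottleneck_dim=4, n_clusters=3, batch_size=64)
        losses = []
        for _ in range(2):
            m = ZINBAutoencoder(expr.values.shape[1], cfg, seed=5)
            losses.append(m.pretrain(expr, raw, epochs=2, seed=5))
        assert losses[0] == losses[1]

    def test_cluster_training_recovers_separated_clusters(self, tiny_processed):
        from sklearn.cluster import KMeans

        from scdistill.metrics import evaluate

        expr, raw = tiny_processed
        cfg = EncoderConfig(layer_sizes=[64, 32], bottleneck_dim=8, n_clusters=3,
                            batch_size=64)
        m = ZINBAutoencoder(expr.values.shape[1], cfg, seed=0)
        m.pretrain(expr, raw, epochs=40, seed=0)
        Z, sa = m.train_cluster(expr, raw, epochs=10, seed=0)
        np.testing.assert_allclose(sa.Q.sum(axis=1), 1.0, atol=1e-6)
        labels = KMeans(3, n_init=10, random_state=0).fit(Z).labels_
        assert evaluate(labels, np.asarray(raw.labels)).ari >= 0.9

    def test_gamma_zero_is_plain_autoencoder(self, tiny_processed):
        expr, raw = tiny_processed
        cfg = EncoderConfig(layer_sizes=[32], bottleneck_dim=4, gamma=0.0,
                            n_clusters=2, batch_size=64)
        m = ZINBAutoencoder(expr.values.shape[1], cfg, seed=0)
        m.pretrain(expr, raw, epochs=1, seed=0)
        Z, _ = m.train_cluster(expr, raw, epochs=1, seed=0)
        assert np.all(np.isfinite(Z))

    def test_too_many_clusters_rejected(self, tiny_processed):
        expr, raw = tiny_processed
        cfg = EncoderConfig(layer_sizes=[32], bottleneck_dim=4,
                            n_clusters=expr.n_cells + 1, batch_size=64)
        m = ZINBAutoencoder(expr.values.shape[1], cfg, seed=0)
        with pytest.raises(ValueError):
            m.init_centers(expr.values)

    def test_reconstruct_returns_valid_zinb_params(self, small_model, tiny_processed):
        expr, _ = tiny_processed
        params = small_model.reconstruct(expr.values, expr.size_factors)
        assert params.mu.shape == expr.values.shape  # invariants checked on init


def test_checkpoint_roundtrip(tmp_path, small_model, tiny_processed):
    expr, _ = tiny_processed
    p = tmp_path / "ck.npz"
    small_model.save_checkpoint(p)
    loaded = type(small_model).load_checkpoint(p)
    np.testing.assert_array_equal(small_model.embed(expr.values), loaded.embed(expr.values))
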