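"""Denoising autoencoder with ZINB reconstruction and DEC-style self-training.

The count model is the zero-inflated negative binomial

    NB(x | mu, theta)   = Gamma(x+theta) / (x! Gamma(theta))
                          * (theta/(theta+mu))^theta * (mu/(theta+mu))^x
    ZINB(x | pi, mu, theta) = pi * 1[x=0] + (1-pi) * NB(x | mu, theta)

where ``pi`` is the dropout (technical zero) probability. The decoder emits
mu (exponential link, scaled by per-cell size factors), theta (softplus) and
pi (sigmoid) per cell and gene; the loss is the mean negative log ZINB
likelihood of the raw counts given a Gaussian-corrupted input (denoising).

Clustering self-training follows deep embedded clustering: soft assignments
q_ij of bottleneck embeddings to cluster centres under a Student-t kernel
(one degree of freedom), sharpened toward the target distribution
p_ij ∝ q_ij² / f_j (f_j the soft cluster frequency), with the KL divergence
KL(P||Q) added to the reconstruction loss weighted by ``gamma``. Centres
are initialised by K-means on the pretrained bottleneck and trained jointly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special
from sklearn.cluster import KMeans

from .io_preprocess import CountMatrix, ExpressionMatrix
from .nnet import MLP, Adam, Tensor, logaddexp, where

logger = logging.getLogger(__name__)

_EPS = 1e-10
_THETA_MIN, _THETA_MAX = 1e-4, 1e4

__all__ = [
    "EncoderConfig",
    "SoftAssignment",
    "ZINBParams",
    "corrupt",
    "zinb_nll",
    "soft_assign",
    "target_distribution",
    "clustering_kl",
    "ZINBAutoencoder",
]


@dataclass
class ZINBParams:
    """Decoder output: per-cell-per-gene ZINB parameters."""

    mu: np.ndarray
    theta: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if not (self.mu.shape == self.theta.shape == self.pi.shape):
            raise ValueError("mu, theta, pi must share a shape")
        if np.any(self.mu <= 0) or np.any(self.theta <= 0):
            raise ValueError("mu and theta must be positive")
        if np.any((self.pi < 0) | (self.pi > 1)):
            raise ValueError("pi must lie in [0, 1]")


@dataclass
class EncoderConfig:
    layer_sizes: list[int] = field(default_factory=lambda: [256, 64])
    bottleneck_dim: int = 32
    noise_sigma: float = 1.5
    cascade_noise: bool = False
    gamma: float = 1.0
    theta_mode: str = "per_gene"  # "per_gene" (DCA-style) or "per_entry"
    n_clusters: int = 8
    batch_size: int = 128
    lr: float = 1e-3
    corrupt_during_cluster: bool = True

    def __post_init__(self):
        if self.bottleneck_dim < 2:
            raise ValueError("bottleneck_dim must be >= 2")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class SoftAssignment:
    Q: np.ndarray  # cells × clusters, rows sum to 1
    centers: np.ndarray  # clusters × bottleneck_dim

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=np.float64)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("soft assignment rows must sum to 1")


# ---------------------------------------------------------------------------
# stateless operations
# ---------------------------------------------------------------------------


def corrupt(X: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Additive i.i.d. Gaussian corruption X + e, e ~ N(0, sigma²)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    X = np.asarray(X, dtype=np.float64)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, sigma, size=X.shape)


def _nb_log_pmf(x, mu, theta):
    # log-gamma form; mu, theta strictly positive by ZINBParams invariants
    return (
        special.gammaln(x + theta)
        - special.gammaln(theta)
        - special.gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + x * (np.log(mu) - np.log(theta + mu))
    )


def zinb_nll(x, params: ZINBParams, reduce: str = "mean"):
    """Negative log ZINB likelihood, computed in log-space.

    The zero-count entries mix the dropout point mass with the NB mass at
    zero through a log-sum-exp; pi = 0 and pi = 1 are handled exactly via
    the usual -inf log conventions. ``reduce`` is one of ``"mean"``
    (default), ``"sum"`` or ``"none"`` (per-entry array).
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("counts must be non-negative integers")
    mu, theta, pi = params.mu, params.theta, params.pi
    log_nb = _nb_log_pmf(x, mu, theta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)  # -inf at pi = 0 is exact under logaddexp
        log_1mpi = np.log1p(-pi)
    case_zero = np.logaddexp(np.broadcast_to(log_pi, log_nb.shape), log_1mpi + log_nb)
    case_nonzero = log_1mpi + log_nb
    nll = -np.where(x == 0, case_zero, case_nonzero)
    if reduce == "mean":
        return float(nll.mean())
    if reduce == "sum":
        return float(nll.sum())
    return nll


def soft_assign(Z: np.ndarray, centers: np.ndarray) -> SoftAssignment:
    """Student-t (df=1) soft assignment of embeddings to cluster centres."""
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    kernel = 1.0 / (1.0 + d2)
    Q = kernel / kernel.sum(axis=1, keepdims=True)
    return SoftAssignment(Q=Q, centers=centers)


def target_distribution(Q) -> np.ndarray:
    """DEC target: p_ij ∝ q_ij² / f_j with f_j = Σ_i q_ij, row-normalised."""
    Q = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)
    if np.any(f < _EPS):
        warnings.warn("empty soft cluster in target_distribution; epsilon-guarded")
    W = Q ** 2 / np.maximum(f, _EPS)
    return W / W.sum(axis=1, keepdims=True)


def clustering_kl(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) = Σ_ij p_ij log(p_ij / q_ij), with 0·log0 = 0."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("P and Q must share a shape")
    if np.any((Q < _EPS) & (P > 0)):
        warnings.warn("Q has (near-)zero mass where P is positive; epsilon-guarded")
    mask = P > 0
    terms = np.zeros_like(P)
    terms[mask] = P[mask] * (np.log(P[mask]) - np.log(np.maximum(Q[mask], _EPS)))
    return float(terms.sum())


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class ZINBAutoencoder:
    """Symmetric fully connected encoder/decoder with ZINB heads."""

    def __init__(self, n_genes: int, cfg: EncoderConfig, seed: int = 0):
        self.cfg = cfg
        self.n_genes = n_genes
        rng = np.random.default_rng(seed)
        enc_sizes = [n_genes, *cfg.layer_sizes, cfg.bottleneck_dim]
        dec_sizes = [cfg.bottleneck_dim, *reversed(cfg.layer_sizes)]
        # training runs in float32; public likelihood/assignment ops stay float64
        self.encoder = MLP(enc_sizes, rng, dtype=np.float32)
        self.decoder_body = MLP(dec_sizes, rng, dtype=np.float32)
        hidden = dec_sizes[-1]
        from .nnet import Dense

        self.head_mu = Dense(hidden, n_genes, rng, dtype=np.float32)
        if cfg.theta_mode == "per_gene":
            self.head_theta = None
            self.theta_log = Tensor(np.zeros(n_genes, dtype=np.float32), requires_grad=True)
        elif cfg.theta_mode == "per_entry":
            self.head_theta = Dense(hidden, n_genes, rng, dtype=np.float32)
        else:
            raise ValueError("theta_mode must be 'per_gene' or 'per_entry'")
        self.head_pi = Dense(hidden, n_genes, rng, dtype=np.float32)
        self.centers: Optional[Tensor] = None
        self.loss_log: list[dict] = []

    # -- forward -----------------------------------------------------------
    @property
    def params(self):
        ps = self.encoder.params + self.decoder_body.params
        ps += self.head_mu.params + self.head_pi.params
        ps += self.head_theta.params if self.head_theta is not None else [self.theta_log]
        return ps

    def _decode(self, z: Tensor, size_factors: np.ndarray):
        h = self.decoder_body(z)
        if len(self.decoder_body.layers):
            h = h.relu()
        log_mu = self.head_mu(h).clip(-12.0, 12.0)
        mu = log_mu.exp() * Tensor(size_factors[:, None])
        theta_pre = self.head_theta(h) if self.head_theta is not None else self.theta_log
        theta = theta_pre.softplus().clip(_THETA_MIN, _THETA_MAX)
        pi = self.head_pi(h).sigmoid()
        return mu, theta, pi

    def _zinb_nll_t(self, x: np.ndarray, mu: Tensor, theta: Tensor, pi: Tensor,
                    lgamma_x1: Optional[np.ndarray] = None) -> Tensor:
        if lgamma_x1 is None:
            lgamma_x1 = special.gammaln(x + 1.0)
        log_nb = (
            (Tensor(x) + theta).lgamma()
            - theta.lgamma()
            - Tensor(lgamma_x1)
            + theta * ((theta + _EPS).log() - (theta + mu + _EPS).log())
            + Tensor(x) * ((mu + _EPS).log() - (theta + mu + _EPS).log())
        )
        log_1mpi = (1.0 - pi + _EPS).log()
        case_zero = logaddexp((pi + _EPS).log(), log_1mpi + log_nb)
        case_nonzero = log_1mpi + log_nb
        return -where(x == 0, case_zero, case_nonzero).mean()

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Bottleneck embedding of (clean) input."""
        return self.encoder.forward_np(np.asarray(X, dtype=np.float64))

    def reconstruct(self, X: np.ndarray, size_factors: np.ndarray) -> ZINBParams:
        z = Tensor(self.embed(X))
        mu, theta, pi = self._decode(z, size_factors)
        theta_full = np.broadcast_to(theta.data, mu.data.shape)
        return ZINBParams(mu=mu.data, theta=theta_full, pi=pi.data)

    # -- training ----------------------------------------------------------
    def _encode_corrupted(self, xb: np.ndarray, rng: np.random.Generator,
                          corrupted: bool) -> Tensor:
        sigma = self.cfg.noise_sigma if corrupted else 0.0
        xb = np.asarray(xb, dtype=np.float32)
        if sigma > 0:
            xb = xb + sigma * rng.standard_normal(xb.shape, dtype=np.float32)
        if not self.cfg.cascade_noise or sigma == 0:
            return self.encoder(Tensor(xb))
        # cascaded variant: inject noise after every hidden layer too
        h = Tensor(xb)
        for i, layer in enumerate(self.encoder.layers):
            h = layer(h)
            if i < len(self.encoder.layers) - 1:
                h = h.relu()
                h = h + Tensor(sigma * rng.standard_normal(h.shape, dtype=np.float32))
        return h

    def pretrain(self, expr: ExpressionMatrix, raw: CountMatrix,
                 epochs: int = 40, seed: int = 0) -> float:
        """Denoising ZINB pretraining; returns the final epoch's mean loss."""
        X = expr.values.astype(np.float32)
        counts = raw.dense().astype(np.float32)
        if counts.shape != X.shape:
            raise ValueError("raw counts must be restricted to the HVG set")
        sf = expr.size_factors.astype(np.float32)
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, lr=self.cfg.lr)
        n = X.shape[0]
        lgx1 = special.gammaln(counts + 1.0)
        last = np.inf
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start:start + self.cfg.batch_size]
                z = self._encode_corrupted(X[idx], rng, corrupted=True)
                mu, theta, pi = self._decode(z, sf[idx])
                loss = self._zinb_nll_t(counts[idx], mu, theta, pi, lgx1[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"ZINB pretraining diverged (NaN/inf loss) at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            last = float(np.mean(losses))
            self.loss_log.append({"stage": "pretrain", "epoch": epoch, "loss": last})
        return last

    def init_centers(self, X: np.ndarray, seed: int = 0) -> np.ndarray:
        """K-means on the pretrained bottleneck to initialise centres."""
        Z = self.embed(X)
        if self.cfg.n_clusters > Z.shape[0]:
            raise ValueError("n_clusters exceeds the number of cells")
        km = KMeans(n_clusters=self.cfg.n_clusters, n_init=10, random_state=seed)
        km.fit(Z)
        self.centers = Tensor(km.cluster_centers_.astype(np.float32), requires_grad=True)
        return self.centers.data

    def _soft_assign_t(self, z: Tensor) -> Tensor:
        c = self.centers
        zz = (z * z).sum(axis=1, keepdims=True)  # n×1
        cc = (c * c).sum(axis=1).reshape(1, -1)  # 1×k
        d2 = zz + cc - 2.0 * (z @ c.T)
        kernel = 1.0 / (1.0 + d2.clip(0.0, np.inf))
        return kernel / kernel.sum(axis=1, keepdims=True)

    def train_cluster(self, expr: ExpressionMatrix, raw: CountMatrix,
                      epochs: int = 20, seed: int = 0):
        """Joint ZINB + gamma·KL(P||Q) training (P refreshed per batch).

        Returns (embeddings, SoftAssignment) on the clean full data.
        """
        X = expr.values.astype(np.float32)
        counts = raw.dense().astype(np.float32)
        sf = expr.size_factors.astype(np.float32)
        if self.centers is None:
            self.init_centers(X, seed=seed)
        rng = np.random.default_rng(seed + 1)
        opt = Adam(self.params + [self.centers], lr=self.cfg.lr)
        n = X.shape[0]
        lgx1 = special.gammaln(counts + 1.0)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start:start + self.cfg.batch_size]
                z = self._encode_corrupted(
                    X[idx], rng, corrupted=self.cfg.corrupt_during_cluster
                )
                mu, theta, pi = self._decode(z, sf[idx])
                loss = self._zinb_nll_t(counts[idx], mu, theta, pi, lgx1[idx])
                if self.cfg.gamma > 0:
                    Qt = self._soft_assign_t(z)
                    P = target_distribution(Qt.data).astype(np.float32)
                    kl = (Tensor(P) * (Tensor(np.log(P + _EPS)) - (Qt + _EPS).log())).sum() * (
                        1.0 / len(idx)
                    )
                    loss = loss + self.cfg.gamma * kl
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"cluster training diverged (NaN/inf loss) at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.loss_log.append(
                {"stage": "cluster", "epoch": epoch, "loss": float(np.mean(losses))}
            )
        Z = self.embed(X)
        assignment = soft_assign(Z, self.centers.data)
        return Z, assignment

    # -- persistence -------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        """Weights + config archive (.npz with an embedded JSON config)."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        if self.centers is not None:
            arrays["centers"] = self.centers.data
        arrays["config_json"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.cfg)).encode(), dtype=np.uint8
        )
        arrays["n_genes"] = np.asarray(self.n_genes)
        np.savez(path, **arrays)

    @classmethod
    def load_checkpoint(cls, path) -> "ZINBAutoencoder":
        with np.load(path) as data:
            cfg = EncoderConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(int(data["n_genes"]), cfg, seed=0)
            for i, p in enumerate(model.params):
                p.data = data[f"p{i}"].astype(p.data.dtype)
            if "centers" in data:
                model.centers = Tensor(data["centers"].astype(np.float32),
                                       requires_grad=True)
        return model
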