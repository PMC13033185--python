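"""Neighbourhood-enhanced momentum contrastive learning.

A query encoder is trained by gradient descent while a key encoder of
identical architecture follows it as an exponential moving average
(momentum update). Each cell contributes two positives — its own corrupted
view through the key encoder, and the key embeddings of its K nearest
neighbours in expression space — combined in a hybrid InfoNCE loss:

    L_i = -log [ exp((1-λ)·q·k_i/τ) + exp(λ·q·k_ic/τ) ]
               / [ (the two positive terms) + Σ_j exp(q·k_j⁻/τ) ]
          + α·‖q_raw‖₁

Negatives k⁻ come from a FIFO queue of past key embeddings. All
representations are L2-normalised before the dot products; the L1 penalty
acts on the pre-normalisation query representation to encourage sparsity.

A configuration flag reproduces the variant without the positive terms in
the denominator; the default keeps them so the loss is a proper
−log-probability bounded below by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .nnet import MLP, Adam, Tensor, logaddexp
from .zinb_autoencoder import corrupt

__all__ = [
    "ContrastiveConfig",
    "DynamicEncoderState",
    "NeighborIndex",
    "momentum_update",
    "build_knn",
    "info_nce",
    "hybrid_info_nce",
    "contrastive_step_loss",
    "train_contrastive",
]


@dataclass
class ContrastiveConfig:
    tau: float = 0.2
    lambda_mix: float = 0.5
    alpha_l1: float = 1e-4
    k_neighbors: int = 5
    refresh_knn_every: int = 0  # epochs between KNN rebuilds in embedding space (0: static)
    queue_size: int = 1024
    momentum: float = 0.999
    noise_sigma: float = 0.5
    epochs: int = 15
    batch_size: int = 128
    lr: float = 1e-3
    head_hidden: int = 64
    head_out: int = 32
    use_mlp_head: bool = True
    printed_denominator: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must lie in [0, 1]")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")


@dataclass
class NeighborIndex:
    neighbor_ids: np.ndarray  # cells × k
    distances: np.ndarray  # cells × k

    def __post_init__(self):
        self.neighbor_ids = np.asarray(self.neighbor_ids, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        n, k = self.neighbor_ids.shape
        if k < 1:
            raise ValueError("k must be >= 1")
        if np.any(self.neighbor_ids == np.arange(n)[:, None]):
            raise ValueError("a cell may not be its own neighbour")


@dataclass
class DynamicEncoderState:
    """Query/key encoder pair with projection heads; shapes match pairwise."""

    query_encoder: MLP
    key_encoder: MLP
    query_head: Optional[MLP]
    key_head: Optional[MLP]
    momentum_m: float

    def __post_init__(self):
        if not 0.0 <= self.momentum_m <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        for a, b in zip(self._query_params(), self._key_params()):
            if a.data.shape != b.data.shape:
                raise ValueError("query and key weight shapes differ")

    def _query_params(self):
        ps = list(self.query_encoder.params)
        if self.query_head is not None:
            ps += self.query_head.params
        return ps

    def _key_params(self):
        ps = list(self.key_encoder.params)
        if self.key_head is not None:
            ps += self.key_head.params
        return ps


def momentum_update(state: DynamicEncoderState) -> DynamicEncoderState:
    """key ← m·key + (1−m)·query for every weight; query untouched."""
    m = state.momentum_m
    for q, k in zip(state._query_params(), state._key_params()):
        k.data = m * k.data + (1.0 - m) * q.data
    return state


def build_knn(X: np.ndarray, k: int) -> NeighborIndex:
    """Euclidean k-nearest neighbours of every cell, excluding itself."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, ids = nn.kneighbors(X)
    # drop the self column; with exact duplicates the self index may appear
    # in any of the tied columns, so remove it explicitly per row
    out_ids = np.empty((n, k), dtype=np.int64)
    out_dist = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        row = ids[i]
        mask = row != i
        if mask.sum() == k + 1:  # self not returned among ties
            mask[-1] = False
        out_ids[i] = row[mask][:k]
        out_dist[i] = dist[i][mask][:k]
    return NeighborIndex(neighbor_ids=out_ids, distances=out_dist)


# ---------------------------------------------------------------------------
# losses (reference numpy implementations, shared by the training loop's
# autodiff path through identical formulas)
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError(f"{name} contains a zero-norm vector")
    return v / norm


def info_nce(q, k_pos, k_negs, tau: float) -> float:
    """Plain InfoNCE: one positive against M negatives at temperature tau."""
    q = _unit(q, "q")
    k_pos = _unit(k_pos, "k_pos")
    s_pos = float(q @ k_pos)
    k_negs = np.atleast_2d(np.asarray(k_negs, dtype=np.float64))
    if k_negs.size == 0:
        return 0.0
    k_negs = _unit(k_negs, "k_negs")
    s_neg = k_negs @ q
    logits = np.concatenate(([s_pos], s_neg)) / tau
    return float(np.logaddexp.reduce(logits) - logits[0])


def hybrid_info_nce(q, k_i, k_ic, k_negs, cfg: ContrastiveConfig) -> float:
    """Hybrid InfoNCE with the augmented self and the neighbour mean as
    positives; with k>1 neighbours, q·k_ic is the mean similarity."""
    q = _unit(q, "q")
    k_i = _unit(k_i, "k_i")
    k_ic = np.atleast_2d(np.asarray(k_ic, dtype=np.float64))
    if k_ic.size == 0:
        warnings.warn("empty neighbour set; falling back to plain InfoNCE")
        return info_nce(q, k_i, k_negs, cfg.tau)
    k_ic = _unit(k_ic, "k_ic")
    lam, tau = cfg.lambda_mix, cfg.tau
    s_i = float(q @ k_i)
    s_ic = float((k_ic @ q).mean())
    pos = [(1.0 - lam) * s_i / tau, lam * s_ic / tau]
    log_num = np.logaddexp(*pos)
    k_negs = np.atleast_2d(np.asarray(k_negs, dtype=np.float64))
    neg_logits = (
        (_unit(k_negs, "k_negs") @ q) / tau if k_negs.size else np.empty(0)
    )
    if cfg.printed_denominator:
        if neg_logits.size == 0:
            raise ValueError("printed denominator needs at least one negative")
        log_den = np.logaddexp.reduce(neg_logits)
    else:
        log_den = np.logaddexp.reduce(np.concatenate((pos, neg_logits)))
    return float(log_den - log_num)


def contrastive_step_loss(q, k_i, k_ic, k_negs, cfg: ContrastiveConfig,
                          q_raw=None) -> float:
    """Hybrid InfoNCE plus the L1 sparsity penalty on the raw query."""
    base = hybrid_info_nce(q, k_i, k_ic, k_negs, cfg)
    raw = np.asarray(q if q_raw is None else q_raw, dtype=np.float64)
    return float(base + cfg.alpha_l1 * np.abs(raw).sum())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _normalize_t(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    return x / norm


def _key_forward(state: DynamicEncoderState, X: np.ndarray) -> np.ndarray:
    h = state.key_encoder.forward_np(X)
    if state.key_head is not None:
        h = state.key_head.forward_np(h)
    norm = np.linalg.norm(h, axis=1, keepdims=True)
    return h / np.maximum(norm, 1e-12)


def train_contrastive(expr_values: np.ndarray, cfg: ContrastiveConfig,
                      init_encoder: Optional[MLP] = None,
                      bottleneck_dim: int = 32,
                      layer_sizes: Optional[list[int]] = None,
                      loss_log: Optional[list] = None):
    """Train the dynamic encoder pair; returns (embeddings, state).

    The query encoder starts from ``init_encoder`` (typically the ZINB
    stage's pretrained encoder) or fresh weights; the key side starts as a
    copy and thereafter only follows momentum updates. Negatives are a FIFO
    queue of past key embeddings. Returned embeddings are the bottleneck
    output of the clean input under the query encoder.
    """
    X = np.asarray(expr_values, dtype=np.float32)
    n, n_genes = X.shape
    rng = np.random.default_rng(cfg.seed)
    if init_encoder is not None:
        query_encoder = init_encoder.copy()
    else:
        sizes = [n_genes, *(layer_sizes or [256, 64]), bottleneck_dim]
        query_encoder = MLP(sizes, rng, dtype=np.float32)
    out_dim = query_encoder.sizes[-1]
    if cfg.use_mlp_head:
        query_head = MLP([out_dim, cfg.head_hidden, cfg.head_out], rng,
                         dtype=query_encoder.dtype)
    else:
        query_head = None
    state = DynamicEncoderState(
        query_encoder=query_encoder,
        key_encoder=query_encoder.copy(),
        query_head=query_head,
        key_head=query_head.copy() if query_head is not None else None,
        momentum_m=cfg.momentum,
    )
    queue_size = int(min(cfg.queue_size, n))
    if queue_size < cfg.batch_size and n >= cfg.batch_size:
        raise ValueError("queue_size must be >= batch_size")
    knn = build_knn(X, min(cfg.k_neighbors, n - 1))
    # warm the queue with key embeddings of random cells
    queue = _key_forward(state, X[rng.integers(0, n, size=queue_size)])
    params = list(query_encoder.params)
    if query_head is not None:
        params += query_head.params
    opt = Adam(params, lr=cfg.lr)
    lam, tau = cfg.lambda_mix, cfg.tau
    for epoch in range(cfg.epochs):
        if cfg.refresh_knn_every > 0 and epoch > 0 and epoch % cfg.refresh_knn_every == 0:
            # rebuild the neighbourhood in the current query embedding space
            knn = build_knn(query_encoder.forward_np(X), min(cfg.k_neighbors, n - 1))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            b = len(idx)
            x_q = corrupt(X[idx], cfg.noise_sigma, int(rng.integers(2 ** 31))).astype(np.float32)
            x_k = corrupt(X[idx], cfg.noise_sigma, int(rng.integers(2 ** 31))).astype(np.float32)
            # query path (autodiff)
            h = query_encoder(Tensor(x_q))
            q_raw = query_head(h) if query_head is not None else h
            q = _normalize_t(q_raw)
            # key paths (no gradient)
            k_i = _key_forward(state, x_k)
            nb = knn.neighbor_ids[idx]  # b × k
            k_nb = _key_forward(state, X[nb.ravel()]).reshape(b, nb.shape[1], -1)
            k_ic = k_nb.mean(axis=1)  # mean similarity == dot with mean key
            s_i = (q * Tensor(k_i)).sum(axis=1, keepdims=True)
            s_ic = (q * Tensor(k_ic)).sum(axis=1, keepdims=True)
            pos_a = (1.0 - lam) * s_i * (1.0 / tau)
            pos_b = lam * s_ic * (1.0 / tau)
            log_num = logaddexp(pos_a, pos_b)
            neg = (q @ Tensor(queue.T)) * (1.0 / tau)  # b × queue
            mx = neg.data.max(axis=1, keepdims=True)
            log_neg = (neg - Tensor(mx)).exp().sum(axis=1, keepdims=True).log() + Tensor(mx)
            if cfg.printed_denominator:
                log_den = log_neg
            else:
                log_den = logaddexp(log_num, log_neg)
            loss = (log_den - log_num).mean()
            if cfg.alpha_l1 > 0:
                loss = loss + cfg.alpha_l1 * q_raw.abs().sum() * (1.0 / b)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"contrastive training diverged at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            momentum_update(state)
            # FIFO: append this batch's key embeddings, evict the oldest
            queue = np.concatenate([queue[b:], k_i], axis=0) if b <= queue_size else k_i[-queue_size:]
            losses.append(float(loss.data))
        if loss_log is not None:
            loss_log.append(
                {"stage": "contrastive", "epoch": epoch, "loss": float(np.mean(losses))}
            )
    embeddings = query_encoder.forward_np(X)
    return embeddings, state
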