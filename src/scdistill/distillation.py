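"""Teacher–student self-knowledge distillation over anchor pseudo-labels.

The teacher reuses the contrastive-pretrained encoder with a linear
classification head and is fitted by cross-entropy on anchor cells only.
The student shares the teacher's architecture (self-distillation), restarts
from the pretrained encoder, and minimises

    L = α·H(p, softmax(z_s/τ1)) + (1-α)·τ2²·KL(softmax(z_t/τ2) ‖ softmax(z_s/τ2))

where the hard targets p are the anchor pseudo-labels (applied on anchors
only, where the labels are trusted) and the softened teacher predictions
supervise every cell. The student's temperature-1 softmax gives the final
probabilistic cluster assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

from .anchor_selection import AnchorSplit
from .nnet import MLP, Adam, Dense, Tensor, log_softmax

__all__ = [
    "KDConfig",
    "ClusterAssignment",
    "Classifier",
    "cross_entropy",
    "kd_loss",
    "train_teacher",
    "train_student",
]

_EPS = 1e-10


@dataclass
class KDConfig:
    alpha_kd: float = 0.5
    tau1: float = 1.0
    tau2: float = 4.0
    epochs_teacher: int = 150
    epochs_student: int = 30
    batch_size: int = 128
    lr: float = 1e-3
    lr_head: float = 5e-2  # linear-probe rate for frozen-encoder teacher
    train_teacher_encoder: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("temperatures must be positive")
        if not 0.0 <= self.alpha_kd <= 1.0:
            raise ValueError("alpha_kd must lie in [0, 1]")


@dataclass
class ClusterAssignment:
    hard_labels: np.ndarray
    soft_probs: np.ndarray

    def __post_init__(self):
        self.hard_labels = np.asarray(self.hard_labels, dtype=np.int64)
        self.soft_probs = np.asarray(self.soft_probs, dtype=np.float64)
        if not np.allclose(self.soft_probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("soft probability rows must sum to 1")
        if not np.array_equal(self.hard_labels, self.soft_probs.argmax(axis=1)):
            raise ValueError("hard labels must be the argmax of soft rows")

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "ClusterAssignment":
        probs = np.asarray(probs, dtype=np.float64)
        return cls(hard_labels=probs.argmax(axis=1), soft_probs=probs)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _log_softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - special.logsumexp(z, axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, logits: np.ndarray) -> float:
    """Mean −Σ_c p_c log softmax(logits)_c over cells."""
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("targets must be row-stochastic")
    return float(-(p * _log_softmax_np(logits)).sum(axis=1).mean())


def kd_loss(hard: np.ndarray, teacher_logits: np.ndarray,
            student_logits: np.ndarray, cfg: KDConfig) -> float:
    """Distillation loss: hard CE at τ1 plus τ2²-scaled teacher→student KL."""
    hard = np.atleast_2d(np.asarray(hard, dtype=np.float64))
    t = np.atleast_2d(np.asarray(teacher_logits, dtype=np.float64))
    s = np.atleast_2d(np.asarray(student_logits, dtype=np.float64))
    ce = cross_entropy(hard, s / cfg.tau1)
    log_qt = _log_softmax_np(t / cfg.tau2)
    log_qs = _log_softmax_np(s / cfg.tau2)
    qt = np.exp(log_qt)
    kl = float((qt * (log_qt - log_qs)).sum(axis=1).mean())
    return cfg.alpha_kd * ce + (1.0 - cfg.alpha_kd) * cfg.tau2 ** 2 * kl


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class Classifier:
    """Encoder + linear classification head."""

    def __init__(self, encoder: MLP, n_classes: int, seed: int = 0):
        self.encoder = encoder
        rng = np.random.default_rng(seed)
        self.head = Dense(encoder.sizes[-1], n_classes, rng, dtype=encoder.dtype)
        self.n_classes = n_classes

    def logits_np(self, X: np.ndarray) -> np.ndarray:
        return self.head.forward_np(self.encoder.forward_np(X))

    def logits_t(self, X: np.ndarray) -> Tensor:
        return self.head(self.encoder(Tensor(X)))

    def predict_probs(self, X: np.ndarray, tau: float = 1.0) -> np.ndarray:
        return np.exp(_log_softmax_np(self.logits_np(X) / tau))

    def weight_shapes(self) -> list[tuple]:
        return [p.data.shape for p in self.encoder.params + self.head.params]


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_teacher(encoder: MLP, anchors: AnchorSplit, expr_values: np.ndarray,
                  cfg: KDConfig) -> Classifier:
    """Fit the classification head (and optionally the encoder) on anchors."""
    labels = anchors.pseudo_labels
    n_classes = int(labels.max()) + 1
    anchor_idx = np.where(anchors.is_anchor)[0]
    present = np.unique(labels[anchor_idx])
    if len(present) < n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        raise ValueError(f"pseudo-classes without anchors: {missing}")
    model = Classifier(encoder.copy(), n_classes, seed=cfg.seed)
    if cfg.train_teacher_encoder:
        opt = Adam(model.head.params + model.encoder.params, lr=cfg.lr)
    else:
        opt = Adam(model.head.params, lr=cfg.lr_head)
    rng = np.random.default_rng(cfg.seed)
    X = np.asarray(expr_values, dtype=np.float32)
    targets = _one_hot(labels[anchor_idx], n_classes).astype(np.float32)
    # frozen encoder: embed the anchors once, train only the linear head
    frozen = None if cfg.train_teacher_encoder else model.encoder.forward_np(X[anchor_idx])
    for _ in range(cfg.epochs_teacher):
        order = rng.permutation(len(anchor_idx))
        for start in range(0, len(anchor_idx), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            if frozen is None:
                logits = model.logits_t(X[anchor_idx[sel]])
            else:
                logits = model.head(Tensor(frozen[sel]))
            loss = -(Tensor(targets[sel]) * log_softmax(logits)).sum(axis=1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def train_student(teacher: Classifier, anchors: AnchorSplit,
                  expr_values: np.ndarray, cfg: KDConfig,
                  init_encoder: Optional[MLP] = None) -> tuple[ClusterAssignment, Classifier]:
    """Distil the teacher into an identically shaped student on all cells."""
    X = np.asarray(expr_values, dtype=np.float32)
    n = X.shape[0]
    n_classes = teacher.n_classes
    encoder = (init_encoder or teacher.encoder).copy()
    student = Classifier(encoder, n_classes, seed=cfg.seed + 1)
    assert student.weight_shapes() == teacher.weight_shapes()
    teacher_logits = teacher.logits_np(X).astype(np.float64)
    log_qt = _log_softmax_np(teacher_logits / cfg.tau2).astype(np.float32)
    qt = np.exp(log_qt)
    labels = anchors.pseudo_labels
    hard = _one_hot(np.clip(labels, 0, n_classes - 1), n_classes).astype(np.float32)
    anchor_mask = anchors.is_anchor.astype(np.float32)
    opt = Adam(student.encoder.params + student.head.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 2)
    for _ in range(cfg.epochs_student):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = student.logits_t(X[sel])
            b = len(sel)
            # hard term on anchors only, at temperature tau1
            ls1 = log_softmax(logits * (1.0 / cfg.tau1))
            ce_rows = -(Tensor(hard[sel]) * ls1).sum(axis=1)
            m = anchor_mask[sel]
            ce = (ce_rows * Tensor(m)).sum() * (1.0 / max(m.sum(), 1.0))
            # soft term everywhere, teacher as the reference distribution
            ls2 = log_softmax(logits * (1.0 / cfg.tau2))
            kl = (Tensor(qt[sel]) * (Tensor(log_qt[sel]) - ls2)).sum(axis=1).mean()
            loss = cfg.alpha_kd * ce + (1.0 - cfg.alpha_kd) * cfg.tau2 ** 2 * kl
            if not np.isfinite(loss.data):
                raise FloatingPointError("student training diverged (NaN/inf loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
    probs = student.predict_probs(X)
    return ClusterAssignment.from_probs(probs), student
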