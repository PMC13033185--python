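"""Synthetic ZINB count matrices with cluster structure and rare subtypes.

The generator draws cells from a labelled mixture: every cluster shares a
flat background mean, and a disjoint block of marker genes per cluster is
up-shifted by a log2 fold change. Counts are negative-binomial
(gamma–Poisson) with per-cell log-normal depth factors, then zeroed with
probability ``dropout_pi`` to emulate dropout. Cluster proportions may
include rare fractions down to 0.1% of cells — the regime where rare-type
detection is tested.

Three presets fix the study conditions used throughout the test suite:
``easy3`` (1,000 cells, 3 balanced well-separated clusters), ``rare5``
(3,000 cells, proportions 0.40/0.30/0.20/0.09/0.01) and ``hard_overlap``
(weak markers, heavy dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .io_preprocess import CountMatrix

__all__ = ["SimConfig", "simulate_counts", "preset", "write_mtx"]


@dataclass
class SimConfig:
    n_cells: int = 1000
    n_genes: int = 1000
    cluster_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    n_marker_genes: int = 100
    log2_fc: float = 3.0
    base_mean: float = 0.5
    theta_sim: float = 2.0
    dropout_pi: float = 0.3
    depth_variation: float = 0.25
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.cluster_proportions, dtype=np.float64)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if np.any(props * self.n_cells < 1.0):
            raise ValueError("every cluster must expect at least one cell")
        if not 0.0 <= self.dropout_pi < 1.0:
            raise ValueError("dropout_pi must lie in [0, 1)")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)


def simulate_counts(cfg: SimConfig) -> CountMatrix:
    """Draw a labelled cells × genes count matrix; reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_clusters
    props = np.asarray(cfg.cluster_proportions, dtype=np.float64)
    labels = rng.choice(k, size=cfg.n_cells, p=props)
    # deterministic guarantee: every cluster keeps at least one cell, filled
    # from the largest cluster's earliest cells
    for c in range(k):
        if not np.any(labels == c):
            counts_per = np.bincount(labels, minlength=k)
            donor = int(np.argmax(counts_per))
            labels[np.where(labels == donor)[0][0]] = c
    # gene means per cluster: flat background + up-shifted marker block
    means = np.full((k, cfg.n_genes), cfg.base_mean, dtype=np.float64)
    fc = 2.0 ** cfg.log2_fc
    for c in range(k):
        lo = c * cfg.n_marker_genes
        hi = min(lo + cfg.n_marker_genes, cfg.n_genes)
        means[c, lo:hi] = cfg.base_mean * fc
    depth = (
        rng.lognormal(0.0, cfg.depth_variation, size=cfg.n_cells)
        if cfg.depth_variation > 0
        else np.ones(cfg.n_cells)
    )
    mu = means[labels] * depth[:, None]
    # NB via gamma–Poisson: lam ~ Gamma(theta, mu/theta), x ~ Poisson(lam)
    lam = rng.gamma(shape=cfg.theta_sim, scale=mu / cfg.theta_sim)
    counts = rng.poisson(lam).astype(np.float64)
    if cfg.dropout_pi > 0:
        counts[rng.random(counts.shape) < cfg.dropout_pi] = 0.0
    return CountMatrix(
        values=counts,
        cell_ids=[f"cell{i}" for i in range(cfg.n_cells)],
        gene_ids=[f"gene{j}" for j in range(cfg.n_genes)],
        labels=[f"type{c}" for c in labels],
    )


_PRESETS = {
    "easy3": SimConfig(
        n_cells=1000,
        n_genes=1000,
        cluster_proportions=(1 / 3, 1 / 3, 1 / 3),
        n_marker_genes=100,
        log2_fc=3.0,
        base_mean=0.5,
        theta_sim=2.0,
        dropout_pi=0.3,
        depth_variation=0.25,
    ),
    "rare5": SimConfig(
        n_cells=3000,
        n_genes=1000,
        cluster_proportions=(0.40, 0.30, 0.20, 0.09, 0.01),
        n_marker_genes=50,
        log2_fc=3.0,
        base_mean=0.5,
        theta_sim=2.0,
        dropout_pi=0.3,
        depth_variation=0.25,
    ),
    "hard_overlap": SimConfig(
        n_cells=1000,
        n_genes=1000,
        cluster_proportions=(0.25, 0.25, 0.25, 0.25),
        n_marker_genes=80,
        log2_fc=1.5,
        base_mean=0.5,
        theta_sim=1.5,
        dropout_pi=0.6,
        depth_variation=0.25,
    ),
}


def preset(name: str, seed: int = 0) -> SimConfig:
    """Return a documented fixed configuration by name."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return replace(_PRESETS[name], seed=seed)


def write_mtx(counts: CountMatrix, directory) -> None:
    """Write MatrixMarket (genes × rows convention) + sidecar files, so the
    generator doubles as a fixture factory for the loaders."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.csr_matrix(counts.dense().T.astype(np.int64))  # genes × cells on disk
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    (directory / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    (directory / "features.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    if counts.labels is not None:
        (directory / "labels.csv").write_text("\n".join(counts.labels) + "\n")
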