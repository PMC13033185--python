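"""Pseudo-labelling and anchor-cell selection.

Cells are first clustered in embedding space with the Leiden community
detection algorithm on a KNN graph. Within each pseudo-cluster, a per-cell
density is the mean cosine similarity between a cell's embedding and its k
nearest neighbours in the same latent space; the top 40% densest cells per
cluster become anchors — the trusted training set for distillation — and
the remainder the refinement/evaluation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "AnchorSplit",
    "leiden_cluster",
    "leiden_cluster_auto",
    "compute_density",
    "select_anchors",
]

#: resolutions scanned when the pipeline selects one from the data
DEFAULT_RESOLUTION_GRID = (0.05, 0.1, 0.25, 0.5, 1.0)


@dataclass
class AnchorSplit:
    pseudo_labels: np.ndarray  # int per cell
    density: np.ndarray  # real per cell
    is_anchor: np.ndarray  # bool per cell
    anchor_fraction: float

    def __post_init__(self):
        self.pseudo_labels = np.asarray(self.pseudo_labels, dtype=np.int64)
        self.density = np.asarray(self.density, dtype=np.float64)
        self.is_anchor = np.asarray(self.is_anchor, dtype=bool)
        if not np.all(np.isfinite(self.density)):
            raise ValueError("density must be finite")
        for lab in np.unique(self.pseudo_labels):
            mask = self.pseudo_labels == lab
            expected = int(np.ceil(self.anchor_fraction * mask.sum()))
            if int(self.is_anchor[mask].sum()) != expected:
                raise ValueError("anchor count violates the per-cluster ceil rule")


def leiden_cluster(Z: np.ndarray, n_neighbors: int = 15, resolution: float = 1.0,
                   seed: int = 0) -> np.ndarray:
    """Leiden communities of the KNN graph of embeddings.

    Labels are 0-based consecutive integers, ordered by first occurrence so
    the labelling is stable across equivalent partitions.
    """
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be < n_cells")
    if np.allclose(Z, Z[0]):
        warnings.warn("all embeddings identical; returning a single cluster")
        return np.zeros(n, dtype=np.int64)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(Z)
    _, ids = nn.kneighbors(Z)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in ids[i, 1:]}
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership, dtype=np.int64)
    # relabel by first occurrence
    _, first = np.unique(raw, return_index=True)
    remap = {raw[i]: rank for rank, i in enumerate(np.sort(first))}
    return np.asarray([remap[r] for r in raw], dtype=np.int64)


def leiden_cluster_auto(Z: np.ndarray, n_neighbors: int = 15,
                        resolutions=DEFAULT_RESOLUTION_GRID,
                        seed: int = 0) -> tuple[np.ndarray, float]:
    """Leiden with the resolution chosen by mean silhouette width.

    Graph community detection on KNN graphs over-partitions compact,
    well-separated latent clusters at high resolution and merges fine
    structure at low resolution; with no annotation to calibrate against,
    the partition that best respects embedding geometry (highest silhouette
    score) is selected from a small fixed grid. Returns (labels, resolution).
    """
    from sklearn.metrics import silhouette_score

    Z = np.asarray(Z, dtype=np.float64)
    best = None
    for res in resolutions:
        labels = leiden_cluster(Z, n_neighbors=n_neighbors, resolution=res, seed=seed)
        k = int(labels.max()) + 1
        if k < 2 or k >= Z.shape[0]:
            continue
        score = float(silhouette_score(Z, labels))
        if best is None or score > best[0]:
            best = (score, labels, res)
    if best is None:  # every resolution collapsed to one community
        return leiden_cluster(Z, n_neighbors=n_neighbors, resolution=resolutions[-1],
                              seed=seed), resolutions[-1]
    return best[1], best[2]


def compute_density(Z: np.ndarray, k: int = 5) -> np.ndarray:
    """Mean cosine similarity of each cell to its k latent-space neighbours."""
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    if k >= n:
        raise ValueError("k must be < n_cells")
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        bad = np.where(norms == 0)[0].tolist()
        raise ValueError(f"zero-norm embedding for cells {bad}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, ids = nn.kneighbors(Z)
    U = Z / norms[:, None]
    dens = np.empty(n)
    for i in range(n):
        row = ids[i]
        nb = row[row != i][:k]
        if len(nb) < k:  # self hidden among exact ties
            nb = np.concatenate([nb, row[-(k - len(nb)):]])
        dens[i] = float((U[nb] @ U[i]).mean())
    return dens


def select_anchors(labels: np.ndarray, density: np.ndarray,
                   anchor_fraction: float = 0.4) -> AnchorSplit:
    """Per cluster, mark the ceil(fraction × size) densest cells as anchors.

    Ties at the boundary break by cell index (lower index wins).
    """
    labels = np.asarray(labels, dtype=np.int64)
    density = np.asarray(density, dtype=np.float64)
    if labels.shape != density.shape:
        raise ValueError("labels and density must be aligned")
    if not 0.0 < anchor_fraction <= 1.0:
        raise ValueError("anchor_fraction must lie in (0, 1]")
    is_anchor = np.zeros(labels.shape[0], dtype=bool)
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if len(members) == 1:
            warnings.warn(f"cluster {lab} has a single cell; it becomes an anchor")
        n_anchor = int(np.ceil(anchor_fraction * len(members)))
        # stable sort on descending density keeps lower cell index on ties
        ranked = members[np.argsort(-density[members], kind="stable")]
        is_anchor[ranked[:n_anchor]] = True
    return AnchorSplit(
        pseudo_labels=labels,
        density=density,
        is_anchor=is_anchor,
        anchor_fraction=anchor_fraction,
    )
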