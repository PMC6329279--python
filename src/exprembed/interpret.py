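"""Interpretation of embedding dimensions and signature-dimension subtyping.

Dimensions are made interpretable by contrasting sample-group centroids
(which dimensions run "hot" for a group), extracting the top genes along a
dimension for over-representation analysis, and mapping signature genes to
the dimension they load most heavily on. Samples restricted to signature
dimensions are clustered with UPGMA (average-linkage agglomerative
clustering on Euclidean distances) to define molecular subtypes.

Dimension indices are 0-based internally; reports label them 1..m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .io import SampleAnnotation
from .model import EmbeddingModel

__all__ = [
    "DimensionGroupMatrix",
    "group_dimension_matrix",
    "hot_dimensions",
    "top_genes_by_dimension",
    "select_signature_dimensions",
    "dimension_sd_filter",
    "upgma_cluster",
    "signature_subtype",
]


@dataclass(frozen=True)
class DimensionGroupMatrix:
    """Group centroids with respect to embedding dimensions: one row per
    sample group, one column per dimension."""

    group_labels: list[str]
    centroids: np.ndarray  # (n_groups, m)

    def row(self, group_label: str) -> np.ndarray:
        try:
            return self.centroids[self.group_labels.index(group_label)]
        except ValueError:
            raise KeyError(f"unknown group label: {group_label!r}") from None


def group_dimension_matrix(
    model: EmbeddingModel, annotations: Iterable[SampleAnnotation]
) -> DimensionGroupMatrix:
    """Per-group centroid of sample vectors; groups ordered by label."""
    label_of = {a.sample_id: a.group_label for a in annotations}
    missing = [s for s in model.sample_ids if s not in label_of]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(model.sample_ids):
        groups.setdefault(label_of[sid], []).append(i)
    labels = sorted(groups)
    centroids = np.stack([model.S[groups[g]].mean(axis=0) for g in labels])
    return DimensionGroupMatrix(group_labels=labels, centroids=centroids)


def hot_dimensions(
    dgm: DimensionGroupMatrix, group_label: str, top_n: int = 5
) -> list[tuple[int, float]]:
    """Dimensions where ``group_label`` deviates most from the other groups.

    Score per dimension: (group coordinate - mean of other groups'
    coordinates) / across-group standard deviation of that coordinate
    (population sd; 0 when all groups coincide). Returns the ``top_n``
    dimensions by |score|, descending, ties broken by lower index.
    """
    if len(dgm.group_labels) < 2:
        raise ValueError("hot_dimensions needs at least 2 groups")
    gi = dgm.group_labels.index(group_label) if group_label in dgm.group_labels else -1
    if gi < 0:
        raise KeyError(f"unknown group label: {group_label!r}")
    c = dgm.centroids
    others = np.delete(c, gi, axis=0)
    sd = c.std(axis=0)
    diff = c[gi] - others.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(sd > 0, diff / np.where(sd > 0, sd, 1.0), 0.0)
    order = sorted(range(c.shape[1]), key=lambda d: (-abs(score[d]), d))
    return [(d, float(score[d])) for d in order[:top_n]]


def top_genes_by_dimension(
    model: EmbeddingModel,
    dimension: int,
    k: int = 100,
    direction: str = "absolute",
) -> list[str]:
    """Top-k genes by their coordinate on one embedding dimension.

    ``direction``: ``positive`` (largest coordinate), ``negative``
    (smallest), or ``absolute`` (largest magnitude). Ties by gene id.
    """
    if not 0 <= dimension < model.dim:
        raise IndexError(f"dimension {dimension} out of range [0, {model.dim})")
    if k > len(model.gene_ids):
        raise ValueError("k exceeds the number of genes")
    coord = model.G[:, dimension]
    if direction == "positive":
        key = -coord
    elif direction == "negative":
        key = coord
    elif direction == "absolute":
        key = -np.abs(coord)
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    order = sorted(range(len(coord)), key=lambda i: (key[i], model.gene_ids[i]))
    return [model.gene_ids[i] for i in order[:k]]


def select_signature_dimensions(
    model: EmbeddingModel, signature_gene_ids: Sequence[str]
) -> dict[str, int]:
    """For each signature gene, the dimension with the largest absolute
    coordinate in its gene vector (ties to the lower index)."""
    out: dict[str, int] = {}
    for gid in signature_gene_ids:
        vec = model.entity_vector(gid, "gene")
        if np.all(vec == 0):
            warnings.warn(f"gene {gid!r} has an all-zero vector; dimension 0 assigned")
        out[gid] = int(np.argmax(np.abs(vec)))
    return out


def dimension_sd_filter(S_sub: np.ndarray) -> list[int]:
    """Keep dimensions whose across-sample standard deviation is strictly
    greater than the mean of all per-dimension standard deviations."""
    S_sub = np.asarray(S_sub, dtype=float)
    if S_sub.ndim != 2 or S_sub.shape[0] < 2:
        raise ValueError("dimension_sd_filter needs >= 2 samples")
    sds = S_sub.std(axis=0)
    return [int(d) for d in np.nonzero(sds > sds.mean())[0]]


def upgma_cluster(
    points: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, np.ndarray]:
    """UPGMA (average-linkage) hierarchical clustering on Euclidean
    distances.

    Returns the scipy-format merge tree (linkage matrix, heights =
    unweighted mean cross-pair distance) and flat 0-based cluster labels
    from cutting the tree to ``n_clusters``, numbered by first appearance.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < 2:
        raise ValueError("upgma_cluster needs >= 2 items")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    Z = linkage(points, method="average", metric="euclidean")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        labels[i] = relabel[r]
    return Z, labels


def signature_subtype(
    model: EmbeddingModel,
    signature_gene_ids: Sequence[str],
    n_clusters: int,
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Subtype samples on signature dimensions: map each signature gene to
    its dimension, restrict sample vectors to those dimensions and cluster
    with UPGMA. Returns (gene -> dimension, linkage matrix, labels)."""
    dims_map = select_signature_dimensions(model, signature_gene_ids)
    dims = sorted(set(dims_map.values()))
    Z, labels = upgma_cluster(model.S[:, dims], n_clusters)
    return dims_map, Z, labels
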