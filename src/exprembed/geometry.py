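"""Distance, neighbor, centroid, analogy and predicted-profile queries
over trained entity matrices.

Relatedness between entities is Euclidean distance in embedding space;
"close neighbors" of an anchor are entities strictly below a distance
threshold (0.1 by default). A sample-group centroid multiplied with the
gene entity matrix yields the group's predicted expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EmbeddingModel

__all__ = [
    "NeighborHit",
    "CentroidProfile",
    "PredictedProfile",
    "distance",
    "close_neighbors",
    "analogy_offset",
    "offset_norm",
    "group_centroid",
    "predicted_profile",
]


@dataclass(frozen=True)
class NeighborHit:
    entity_id: str
    distance: float


@dataclass(frozen=True)
class CentroidProfile:
    """Mean of member sample vectors for a labelled group."""

    group_label: str
    centroid: np.ndarray
    member_count: int
    mean_sample_bias: float = 0.0


@dataclass(frozen=True)
class PredictedProfile:
    """Per-gene scalar prediction under a group centroid."""

    group_label: str
    values: dict[str, float]
    include_biases: bool = False


def distance(model: EmbeddingModel, id_a: str, id_b: str, space: str = "gene") -> float:
    va = model.entity_vector(id_a, space)
    vb = model.entity_vector(id_b, space)
    return float(np.linalg.norm(va - vb))


def close_neighbors(
    model: EmbeddingModel,
    anchor_id: str,
    threshold: float = 0.1,
    space: str = "gene",
) -> list[NeighborHit]:
    """All entities at Euclidean distance strictly below ``threshold`` from
    the anchor, anchor excluded, ascending by distance (ties by id)."""
    ids = model.entity_ids(space)
    mat = model.entity_matrix(space)
    anchor_vec = model.entity_vector(anchor_id, space)
    dists = np.linalg.norm(mat - anchor_vec[None, :], axis=1)
    hits = [
        NeighborHit(entity_id=eid, distance=float(d))
        for eid, d in zip(ids, dists)
        if eid != anchor_id and d < threshold
    ]
    hits.sort(key=lambda h: (h.distance, h.entity_id))
    return hits


def analogy_offset(
    model: EmbeddingModel, id_a: str, id_b: str, space: str = "gene"
) -> np.ndarray:
    """vector(a) - vector(b): the analogy offset between two entities."""
    return model.entity_vector(id_a, space) - model.entity_vector(id_b, space)


def offset_norm(model: EmbeddingModel, id_a: str, id_b: str, space: str = "gene") -> float:
    return float(np.linalg.norm(analogy_offset(model, id_a, id_b, space)))


def group_centroid(
    model: EmbeddingModel,
    sample_ids: list[str],
    group_label: str = "group",
) -> CentroidProfile:
    if not sample_ids:
        raise ValueError("group_centroid needs a non-empty sample list")
    idx = [model.sample_index(s) for s in sample_ids]
    return CentroidProfile(
        group_label=group_label,
        centroid=model.S[idx].mean(axis=0),
        member_count=len(idx),
        mean_sample_bias=float(model.b_sample[idx].mean()),
    )


def predicted_profile(
    model: EmbeddingModel,
    centroid: CentroidProfile,
    include_biases: bool = False,
) -> PredictedProfile:
    """Predicted log2 expression per gene under a group centroid:
    dot(centroid, G_a), plus gene bias and mean member sample bias when
    ``include_biases`` is set."""
    c = np.asarray(centroid.centroid, dtype=float)
    if c.shape != (model.dim,):
        raise ValueError(
            f"centroid dimension {c.shape} does not match model dim {model.dim}"
        )
    vals = model.G @ c
    if include_biases:
        vals = vals + model.b_gene + centroid.mean_sample_bias
    return PredictedProfile(
        group_label=centroid.group_label,
        values={g: float(v) for g, v in zip(model.gene_ids, vals)},
        include_biases=include_biases,
    )
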