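"""Responder/non-responder biomarker discovery.

The workflow contrasts a responder and a non-responder sample group:
each group's centroid in sample-entity space is multiplied with the gene
entity matrix to give a predicted expression profile, genes whose
predicted value lies strictly within a threshold of an anchor gene's
(e.g. an immune checkpoint gene such as PDCD1, CD274 or CTLA4) are its
profile neighbors, and neighbors present exclusively in the responder
profile are intersected with the anchor's close neighbors in gene-entity
space. The surviving genes are candidate biomarkers; a Pearson
correlation of each candidate with the anchor across responder samples
is attached as a sanity check.

Distances in a predicted profile are one-dimensional (one scalar per
gene), so "Euclidean distance" reduces to the absolute difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import PredictedProfile, close_neighbors, group_centroid, predicted_profile
from .io import ExpressionMatrix
from .model import EmbeddingModel

__all__ = [
    "GroupSpec",
    "AnchorResult",
    "CandidateReport",
    "profile_neighbors",
    "exclusive_neighbors",
    "pearson",
    "discover",
]


@dataclass(frozen=True)
class GroupSpec:
    """Responder/non-responder sample lists plus anchor genes."""

    responder_sample_ids: tuple[str, ...]
    nonresponder_sample_ids: tuple[str, ...]
    anchor_gene_ids: tuple[str, ...]
    threshold: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "responder_sample_ids", tuple(self.responder_sample_ids)
        )
        object.__setattr__(
            self, "nonresponder_sample_ids", tuple(self.nonresponder_sample_ids)
        )
        object.__setattr__(self, "anchor_gene_ids", tuple(self.anchor_gene_ids))
        if not self.responder_sample_ids or not self.nonresponder_sample_ids:
            raise ValueError("both sample groups must be non-empty")
        if set(self.responder_sample_ids) & set(self.nonresponder_sample_ids):
            raise ValueError("responder and non-responder sample lists overlap")
        if not self.anchor_gene_ids:
            raise ValueError("at least one anchor gene is required")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class AnchorResult:
    """Discovery output for one anchor gene.

    ``details`` maps each candidate to (profile delta in responders,
    profile delta in non-responders, gene-entity distance, Pearson r on
    responder samples)."""

    anchor: str
    responder_exclusive_neighbors: tuple[str, ...]
    entity_neighbors: tuple[str, ...]
    candidates: tuple[str, ...]
    pearson_r: dict[str, float] = field(default_factory=dict)
    details: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class CandidateReport:
    anchors: dict[str, AnchorResult]
    union_candidates: tuple[str, ...]

    @property
    def union_candidate_count(self) -> int:
        return len(self.union_candidates)


def profile_neighbors(
    profile: PredictedProfile, anchor_gene: str, threshold: float = 0.1
) -> set[str]:
    """Genes whose predicted value lies strictly within ``threshold`` of
    the anchor's (absolute difference; anchor excluded)."""
    if anchor_gene not in profile.values:
        raise KeyError(f"anchor gene {anchor_gene!r} not in profile")
    ref = profile.values[anchor_gene]
    return {
        g
        for g, v in profile.values.items()
        if g != anchor_gene and abs(v - ref) < threshold
    }


def exclusive_neighbors(
    resp_profile: PredictedProfile,
    nonresp_profile: PredictedProfile,
    anchor_gene: str,
    threshold: float = 0.1,
) -> set[str]:
    """Profile neighbors of the anchor present exclusively in the
    responder profile."""
    if set(resp_profile.values) != set(nonresp_profile.values):
        raise ValueError("profiles cover different gene universes")
    return profile_neighbors(resp_profile, anchor_gene, threshold) - profile_neighbors(
        nonresp_profile, anchor_gene, threshold
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation; NaN with a warning on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("pearson needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in pearson input; correlation undefined")
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def discover(
    model: EmbeddingModel,
    expr: ExpressionMatrix,
    spec: GroupSpec,
    include_biases: bool = False,
) -> CandidateReport:
    """Run the full discovery workflow for every anchor gene in ``spec``.

    candidates(anchor) = (responder-profile neighbors \\ non-responder
    profile neighbors) intersected with the anchor's gene-entity close
    neighbors, all at ``spec.threshold``.
    """
    for a in spec.anchor_gene_ids:
        model.gene_index(a)
        if a not in expr.gene_ids:
            raise KeyError(f"anchor gene {a!r} absent from expression matrix")
    c_resp = group_centroid(model, list(spec.responder_sample_ids), "responder")
    c_non = group_centroid(model, list(spec.nonresponder_sample_ids), "nonresponder")
    prof_resp = predicted_profile(model, c_resp, include_biases)
    prof_non = predicted_profile(model, c_non, include_biases)
    resp_rows = [expr.sample_index(s) for s in spec.responder_sample_ids]
    gene_col = {g: j for j, g in enumerate(expr.gene_ids)}

    anchors: dict[str, AnchorResult] = {}
    union: set[str] = set()
    for anchor in spec.anchor_gene_ids:
        excl = exclusive_neighbors(prof_resp, prof_non, anchor, spec.threshold)
        entity = {
            h.entity_id
            for h in close_neighbors(model, anchor, spec.threshold, "gene")
        }
        cands = sorted(excl & entity)
        r_map: dict[str, float] = {}
        det: dict[str, tuple[float, float, float, float]] = {}
        anchor_expr = expr.values[np.ix_(resp_rows, [gene_col[anchor]])].ravel()
        a_vec = model.entity_vector(anchor, "gene")
        for cand in cands:
            if cand in gene_col and len(resp_rows) >= 3:
                c_expr = expr.values[np.ix_(resp_rows, [gene_col[cand]])].ravel()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = pearson(anchor_expr, c_expr)
            else:
                r = float("nan")
            r_map[cand] = r
            det[cand] = (
                abs(prof_resp.values[cand] - prof_resp.values[anchor]),
                abs(prof_non.values[cand] - prof_non.values[anchor]),
                float(np.linalg.norm(model.entity_vector(cand, "gene") - a_vec)),
                r,
            )
        anchors[anchor] = AnchorResult(
            anchor=anchor,
            responder_exclusive_neighbors=tuple(sorted(excl)),
            entity_neighbors=tuple(sorted(entity)),
            candidates=tuple(cands),
            pearson_r=r_map,
            details=det,
        )
        union.update(cands)
    return CandidateReport(anchors=anchors, union_candidates=tuple(sorted(union)))
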