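"""Synthetic expression data with known ground truth.

The generator emulates the structure the embedding model assumes: a
low-rank log2-expression matrix built from latent gene and sample
vectors plus per-gene and per-sample biases and Gaussian noise. Samples
fall into discrete groups (cancer types) whose latent centers are
separated in latent space; genes may belong to planted co-regulated
modules (members share a latent center with a small spread). A constant
shift makes all values non-negative, keeping them on a valid log2 scale
without clipping the planted low-rank structure.

`make_responder_scenario` plants a responder-linked module: the anchor
gene's module is aligned with the responder group's latent direction and
its members are offset from the anchor along the non-responder group's
direction, so they are close to the anchor in gene-entity space and in
the responder predicted profile but not in the non-responder profile —
the ground truth the discovery workflow should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .discovery import GroupSpec
from .enrich import GeneSetCollection
from .io import ExpressionMatrix
from .model import EmbeddingConfig, EmbeddingModel

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate",
    "make_responder_scenario",
    "make_gmt",
    "export_raw_counts",
    "model_from_truth",
    "annotations_of",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``modules`` is a list of (size, latent-center spread) pairs;
    ``group_separation`` is the expected Euclidean distance between group
    centers in latent space; ``sample_jitter`` the isotropic sd of sample
    vectors around their group center; noise and biases are on the log2
    scale.
    """

    n_samples: int = 200
    k_genes: int = 500
    latent_rank: int = 5
    n_groups: int = 4
    group_separation: float = 2.0
    sample_jitter: float = 0.3
    modules: tuple[tuple[int, float], ...] = ((25, 0.05), (25, 0.05))
    noise_sd: float = 0.1
    bias_sd_gene: float = 0.5
    bias_sd_sample: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.k_genes < 1:
            raise ValueError("n_samples and k_genes must be positive")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.noise_sd < 0 or self.bias_sd_gene < 0 or self.bias_sd_sample < 0:
            raise ValueError("standard deviations must be non-negative")
        sizes = [s for s, _ in self.modules]
        if any(s < 1 for s in sizes):
            raise ValueError("module sizes must be positive")
        if sum(sizes) > self.k_genes:
            raise ValueError("module sizes exceed the number of genes")


@dataclass
class SynthTruth:
    """Ground truth behind a generated matrix."""

    G_true: np.ndarray  # (k, r)
    S_true: np.ndarray  # (n, r)
    b_gene: np.ndarray
    b_sample: np.ndarray
    shift: float
    group_of: list[str]  # per sample
    module_of: list[str | None]  # per gene; None = background
    config: SynthConfig
    anchor_id: str | None = None
    planted_candidates: tuple[str, ...] = ()
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def module_genes(self, module_label: str) -> list[str]:
        return [
            g for g, mod in zip(self.gene_ids, self.module_of) if mod == module_label
        ]

    def background_genes(self) -> list[str]:
        return [g for g, mod in zip(self.gene_ids, self.module_of) if mod is None]

    def group_samples(self, group_label: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group_of) if g == group_label]


def _ids(prefix: str, count: int) -> list[str]:
    width = max(4, len(str(count)))
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def _group_assignment(cfg: SynthConfig) -> np.ndarray:
    base, rem = divmod(cfg.n_samples, cfg.n_groups)
    counts = [base + (1 if g < rem else 0) for g in range(cfg.n_groups)]
    return np.repeat(np.arange(cfg.n_groups), counts)


def _assemble(cfg, rng, G_true, S_true, group_idx, module_of):
    b_gene = rng.normal(0.0, cfg.bias_sd_gene, cfg.k_genes)
    b_sample = rng.normal(0.0, cfg.bias_sd_sample, cfg.n_samples)
    X = S_true @ G_true.T + b_sample[:, None] + b_gene[None, :]
    if cfg.noise_sd > 0:
        X = X + rng.normal(0.0, cfg.noise_sd, X.shape)
    shift = float(max(0.0, -X.min()))
    X = X + shift
    gene_ids = _ids("GENE", cfg.k_genes)
    sample_ids = _ids("S", cfg.n_samples)
    group_of = [f"GROUP{g}" for g in group_idx]
    expr = ExpressionMatrix(
        sample_ids=sample_ids, gene_ids=gene_ids, values=X, is_log2=True
    )
    truth = SynthTruth(
        G_true=G_true,
        S_true=S_true,
        b_gene=b_gene,
        b_sample=b_sample,
        shift=shift,
        group_of=group_of,
        module_of=module_of,
        config=cfg,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )
    return expr, truth


def generate(config: SynthConfig) -> tuple[ExpressionMatrix, SynthTruth]:
    """Generate a log2 expression matrix with low-rank structure, sample
    groups, planted gene modules, biases and noise; deterministic in
    ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    r = cfg.latent_rank
    center_sd = cfg.group_separation / np.sqrt(2 * r)
    centers = rng.normal(0.0, center_sd, (cfg.n_groups, r))
    group_idx = _group_assignment(cfg)
    S_true = centers[group_idx] + rng.normal(0.0, cfg.sample_jitter, (cfg.n_samples, r))
    gene_scale = 1.0 / np.sqrt(r)
    G_true = np.empty((cfg.k_genes, r))
    module_of: list[str | None] = [None] * cfg.k_genes
    pos = 0
    for mi, (size, spread) in enumerate(cfg.modules):
        center = rng.normal(0.0, gene_scale, r)
        G_true[pos : pos + size] = center + rng.normal(0.0, spread, (size, r))
        for j in range(pos, pos + size):
            module_of[j] = f"MODULE_{mi}"
        pos += size
    n_bg = cfg.k_genes - pos
    G_true[pos:] = rng.normal(0.0, gene_scale, (n_bg, r))
    return _assemble(cfg, rng, G_true, S_true, group_idx, module_of)


def make_responder_scenario(
    config: SynthConfig | None = None,
    module_effect: float = 1.0,
    responder_spread: float = 0.5,
) -> tuple[ExpressionMatrix, SynthTruth, GroupSpec]:
    """Generate a responder/non-responder contrast with a planted
    anchor-linked module.

    Group 0 is the responder set, group 1 the non-responder set. The
    anchor module's genes sit at ``module_effect`` along the responder
    latent direction, with members offset from the anchor along the
    non-responder direction by slightly less than the 0.1 neighbor
    threshold, and responder samples get extra spread
    (``responder_spread``) along their own direction so module genes
    co-vary with the anchor specifically in responders.
    """
    if module_effect <= 0:
        raise ValueError("module_effect must be positive")
    cfg = config if config is not None else SynthConfig(
        n_groups=3, group_separation=3.0, modules=((10, 0.05), (20, 0.05))
    )
    if cfg.n_groups < 2:
        raise ValueError("responder scenario needs >= 2 groups")
    if cfg.latent_rank < 2:
        raise ValueError("responder scenario needs latent_rank >= 2")
    if not cfg.modules:
        raise ValueError("responder scenario needs >= 1 planted module")
    rng = np.random.default_rng(cfg.seed)
    r = cfg.latent_rank
    alpha = cfg.group_separation / np.sqrt(2.0)
    e1 = np.zeros(r)
    e1[0] = 1.0
    e2 = np.zeros(r)
    e2[1] = 1.0
    centers = np.zeros((cfg.n_groups, r))
    centers[0] = alpha * e1  # responders
    centers[1] = alpha * e2  # non-responders
    if cfg.n_groups > 2:
        center_sd = cfg.group_separation / np.sqrt(2 * r)
        centers[2:] = rng.normal(0.0, center_sd, (cfg.n_groups - 2, r))
    group_idx = _group_assignment(cfg)
    S_true = centers[group_idx] + rng.normal(0.0, cfg.sample_jitter, (cfg.n_samples, r))
    resp_mask = group_idx == 0
    S_true[resp_mask, 0] += rng.normal(0.0, responder_spread, int(resp_mask.sum()))

    gene_scale = 1.0 / np.sqrt(r)
    G_true = np.empty((cfg.k_genes, r))
    module_of: list[str | None] = [None] * cfg.k_genes
    # anchor module: gene 0 is the anchor; members offset along the
    # non-responder direction just inside the neighbor threshold
    size0 = cfg.modules[0][0]
    anchor_vec = module_effect * e1
    G_true[0] = anchor_vec
    eps = rng.uniform(0.065, 0.09, size0 - 1) * rng.choice([-1.0, 1.0], size0 - 1)
    G_true[1:size0] = (
        anchor_vec
        + eps[:, None] * e2
        + rng.normal(0.0, 0.005, (size0 - 1, r))
    )
    for j in range(size0):
        module_of[j] = "MODULE_0"
    pos = size0
    for mi, (size, spread) in enumerate(cfg.modules[1:], start=1):
        center = rng.normal(0.0, gene_scale, r)
        G_true[pos : pos + size] = center + rng.normal(0.0, spread, (size, r))
        for j in range(pos, pos + size):
            module_of[j] = f"MODULE_{mi}"
        pos += size
    G_true[pos:] = rng.normal(0.0, gene_scale, (cfg.k_genes - pos, r))

    expr, truth = _assemble(cfg, rng, G_true, S_true, group_idx, module_of)
    truth.anchor_id = truth.gene_ids[0]
    truth.planted_candidates = tuple(truth.gene_ids[1:size0])
    spec = GroupSpec(
        responder_sample_ids=tuple(truth.group_samples("GROUP0")),
        nonresponder_sample_ids=tuple(truth.group_samples("GROUP1")),
        anchor_gene_ids=(truth.anchor_id,),
        threshold=0.1,
    )
    return expr, truth, spec


def make_gmt(truth: SynthTruth) -> GeneSetCollection:
    """One gene set per planted module; background genes excluded."""
    labels = sorted({m for m in truth.module_of if m is not None})
    if not labels:
        raise ValueError("truth contains no planted modules")
    return GeneSetCollection(
        sets={
            lab: (f"planted module {lab}", tuple(truth.module_genes(lab)))
            for lab in labels
        }
    )


def export_raw_counts(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Invert the log2 transform (2**v) to obtain a raw-count-style table;
    preprocessing it reproduces ``expr`` exactly for values >= 0."""
    if not expr.is_log2:
        raise ValueError("export_raw_counts expects a log2 matrix")
    return ExpressionMatrix(
        sample_ids=list(expr.sample_ids),
        gene_ids=list(expr.gene_ids),
        values=np.exp2(expr.values),
        is_log2=False,
        gene_meta=dict(expr.gene_meta),
    )


def model_from_truth(truth: SynthTruth) -> EmbeddingModel:
    """Package the ground-truth vectors as an EmbeddingModel (the constant
    non-negativity shift is folded into the sample biases so predictions
    match the generated matrix)."""
    cfg = EmbeddingConfig(dim=truth.config.latent_rank, seed=truth.config.seed)
    return EmbeddingModel(
        gene_ids=list(truth.gene_ids),
        sample_ids=list(truth.sample_ids),
        G=truth.G_true.copy(),
        S=truth.S_true.copy(),
        b_gene=truth.b_gene.copy(),
        b_sample=truth.b_sample + truth.shift,
        config=cfg,
    )


def annotations_of(truth: SynthTruth):
    """Sample annotations (group labels) for a generated dataset."""
    from .io import SampleAnnotation

    return [
        SampleAnnotation(sample_id=s, group_label=g)
        for s, g in zip(truth.sample_ids, truth.group_of)
    ]
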