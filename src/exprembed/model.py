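"""The two-layer embedding model and its trainer.

Each gene a and each sample i is represented by an m-dimensional vector
(rows of the gene entity matrix G and sample entity matrix S) plus scalar
biases.  The predicted log2 expression of gene a in sample i is

    G_ai = G_a . S_i + b_a + b_i

i.e. biased matrix factorization, the collaborative-filtering formulation
in which every matrix cell is one training example.  Training minimizes
the mean squared loss over cells with mini-batch Adam; gradients are the
exact analytic gradients of the batch MSE with respect to the rows of G
and S and the biases touched by the batch (lazy Adam: moment estimates
and step counts advance only for touched rows).

A learning-rate range test (`lr_find`) sweeps geometrically increasing
rates over single mini-batches and suggests the rate one order of
magnitude below the loss minimum.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, write_matrix_tsv

__all__ = [
    "EmbeddingConfig",
    "EmbeddingModel",
    "TrainReport",
    "LRFindResult",
    "init_model",
    "predict_cell",
    "predict_matrix",
    "mse",
    "batch_gradients",
    "train",
    "lr_find",
    "save_model",
    "load_model",
    "export_projector",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the embedding model.

    Defaults follow the reference setup: 50 dimensions, mini-batch 64,
    3 epochs, uniform init on [-0.05, 0.05], Adam with standard moments.
    """

    dim: int = 50
    learning_rate: float = 1e-2
    batch_size: int = 64
    epochs: int = 3
    init_half_range: float = 0.05
    seed: int = 0
    validation_fraction: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not self.init_half_range > 0:
            raise ValueError("init_half_range must be positive")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass
class EmbeddingModel:
    """Trained (or initialized) embedding: entity matrices plus biases."""

    gene_ids: list[str]
    sample_ids: list[str]
    G: np.ndarray  # (k, m) gene entity matrix
    S: np.ndarray  # (n, m) sample entity matrix
    b_gene: np.ndarray  # (k,)
    b_sample: np.ndarray  # (n,)
    config: EmbeddingConfig

    def __post_init__(self) -> None:
        k, n, m = len(self.gene_ids), len(self.sample_ids), self.config.dim
        self.G = np.asarray(self.G, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.b_gene = np.asarray(self.b_gene, dtype=float)
        self.b_sample = np.asarray(self.b_sample, dtype=float)
        if self.G.shape != (k, m) or self.S.shape != (n, m):
            raise ValueError("entity matrix shapes inconsistent with ids and dim")
        if self.b_gene.shape != (k,) or self.b_sample.shape != (n,):
            raise ValueError("bias shapes inconsistent with ids")
        for arr in (self.G, self.S, self.b_gene, self.b_sample):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model contains non-finite entries")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def dim(self) -> int:
        return self.config.dim

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def entity_ids(self, space: str) -> list[str]:
        self._check_space(space)
        return self.gene_ids if space == "gene" else self.sample_ids

    def entity_matrix(self, space: str) -> np.ndarray:
        self._check_space(space)
        return self.G if space == "gene" else self.S

    def entity_vector(self, entity_id: str, space: str) -> np.ndarray:
        self._check_space(space)
        if space == "gene":
            return self.G[self.gene_index(entity_id)]
        return self.S[self.sample_index(entity_id)]

    @staticmethod
    def _check_space(space: str) -> None:
        if space not in ("gene", "sample"):
            raise ValueError(f"space must be 'gene' or 'sample', got {space!r}")

    def copy(self) -> "EmbeddingModel":
        return EmbeddingModel(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            G=self.G.copy(),
            S=self.S.copy(),
            b_gene=self.b_gene.copy(),
            b_sample=self.b_sample.copy(),
            config=self.config,
        )


@dataclass
class TrainReport:
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    learning_rate: float = 0.0
    epochs: int = 0
    seed: int = 0


@dataclass
class LRFindResult:
    rates: np.ndarray
    losses: np.ndarray
    smoothed_losses: np.ndarray
    suggested_lr: float
    diverged: bool = False


def init_model(expr: ExpressionMatrix, config: EmbeddingConfig) -> EmbeddingModel:
    """Initialize all weights i.i.d. uniform on [-h, +h] (h = init_half_range),
    deterministically from config.seed."""
    if expr.n_samples == 0 or expr.n_genes == 0:
        raise ValueError("cannot initialize a model on an empty matrix")
    rng = np.random.default_rng(config.seed)
    h = config.init_half_range
    k, n, m = expr.n_genes, expr.n_samples, config.dim
    return EmbeddingModel(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        G=rng.uniform(-h, h, size=(k, m)),
        S=rng.uniform(-h, h, size=(n, m)),
        b_gene=rng.uniform(-h, h, size=k),
        b_sample=rng.uniform(-h, h, size=n),
        config=config,
    )


def predict_cell(model: EmbeddingModel, sample_index: int, gene_index: int) -> float:
    n, k = len(model.sample_ids), len(model.gene_ids)
    if not 0 <= sample_index < n:
        raise IndexError(f"sample index {sample_index} out of range [0, {n})")
    if not 0 <= gene_index < k:
        raise IndexError(f"gene index {gene_index} out of range [0, {k})")
    return float(
        model.G[gene_index] @ model.S[sample_index]
        + model.b_gene[gene_index]
        + model.b_sample[sample_index]
    )


def predict_matrix(model: EmbeddingModel) -> np.ndarray:
    """Full n x k prediction: S G^T plus broadcast biases."""
    return (
        model.S @ model.G.T
        + model.b_sample[:, None]
        + model.b_gene[None, :]
    )


def mse(model: EmbeddingModel, expr: ExpressionMatrix) -> float:
    if (expr.n_samples, expr.n_genes) != (len(model.sample_ids), len(model.gene_ids)):
        raise ValueError("expression matrix dimensions do not match model")
    diff = predict_matrix(model) - expr.values
    return float(np.mean(diff * diff))


def _batch_forward(model, si, gi):
    Gr = model.G[gi]
    Sr = model.S[si]
    pred = np.einsum("ij,ij->i", Gr, Sr) + model.b_gene[gi] + model.b_sample[si]
    return Gr, Sr, pred


def batch_gradients(
    model: EmbeddingModel,
    sample_idx: np.ndarray,
    gene_idx: np.ndarray,
    values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of the batch MSE with respect to every parameter.

    Returns dense arrays (dG, dS, db_gene, db_sample); rows not touched by
    the batch are zero. Used by the trainer and by gradient checks.
    """
    si = np.asarray(sample_idx, dtype=int)
    gi = np.asarray(gene_idx, dtype=int)
    y = np.asarray(values, dtype=float)
    Gr, Sr, pred = _batch_forward(model, si, gi)
    coef = (2.0 / len(y)) * (pred - y)
    dG = np.zeros_like(model.G)
    dS = np.zeros_like(model.S)
    np.add.at(dG, gi, coef[:, None] * Sr)
    np.add.at(dS, si, coef[:, None] * Gr)
    db_gene = np.zeros_like(model.b_gene)
    db_sample = np.zeros_like(model.b_sample)
    np.add.at(db_gene, gi, coef)
    np.add.at(db_sample, si, coef)
    return dG, dS, db_gene, db_sample


class _AdamState:
    """Lazy Adam: moments and step counts advance only for touched rows."""

    def __init__(self, shape):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = np.zeros(shape[0] if isinstance(shape, tuple) else shape, dtype=int)

    def update(self, param, rows, grad, cfg: EmbeddingConfig, lr: float) -> None:
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_epsilon
        self.t[rows] += 1
        self.m[rows] = b1 * self.m[rows] + (1 - b1) * grad
        self.v[rows] = b2 * self.v[rows] + (1 - b2) * grad * grad
        tb = self.t[rows]
        c1 = 1.0 - b1 ** tb
        c2 = 1.0 - b2 ** tb
        if param.ndim == 2:
            c1 = c1[:, None]
            c2 = c2[:, None]
        mhat = self.m[rows] / c1
        vhat = self.v[rows] / c2
        param[rows] -= lr * mhat / (np.sqrt(vhat) + eps)


def _cells_of(expr: ExpressionMatrix):
    n, k = expr.n_samples, expr.n_genes
    idx = np.arange(n * k)
    return idx // k, idx % k, expr.values.ravel()


def _sparse_step(model, states, si, gi, y, cfg, lr):
    """One mini-batch Adam step; returns the pre-update batch loss."""
    Gr, Sr, pred = _batch_forward(model, si, gi)
    err = pred - y
    if not np.all(np.isfinite(err)):
        raise FloatingPointError(
            "training loss became non-finite; try a lower learning rate"
        )
    coef = (2.0 / len(y)) * err
    ug, invg = np.unique(gi, return_inverse=True)
    us, invs = np.unique(si, return_inverse=True)
    dG = np.zeros((len(ug), model.G.shape[1]))
    dS = np.zeros((len(us), model.S.shape[1]))
    np.add.at(dG, invg, coef[:, None] * Sr)
    np.add.at(dS, invs, coef[:, None] * Gr)
    dbg = np.bincount(invg, weights=coef)
    dbs = np.bincount(invs, weights=coef)
    if cfg.weight_decay > 0:
        wd = cfg.weight_decay
        dG += wd * model.G[ug]
        dS += wd * model.S[us]
        dbg += wd * model.b_gene[ug]
        dbs += wd * model.b_sample[us]
    stG, stS, stbg, stbs = states
    stG.update(model.G, ug, dG, cfg, lr)
    stS.update(model.S, us, dS, cfg, lr)
    stbg.update(model.b_gene, ug, dbg, cfg, lr)
    stbs.update(model.b_sample, us, dbs, cfg, lr)
    return float(np.sum(err * err))


def _holdout_split(expr: ExpressionMatrix, cfg: EmbeddingConfig, rng):
    si, gi, y = _cells_of(expr)
    n_cells = len(y)
    perm = rng.permutation(n_cells)
    n_val = int(round(cfg.validation_fraction * n_cells))
    return (si, gi, y), perm[n_val:], perm[:n_val]


def train(
    expr: ExpressionMatrix,
    config: EmbeddingConfig,
    initial_model: EmbeddingModel | None = None,
) -> tuple[EmbeddingModel, TrainReport]:
    """Train the embedding by mini-batch Adam on individual matrix cells.

    Each epoch shuffles the training cells with the seeded generator and
    consumes them in batches of ``config.batch_size``. A seeded random
    ``validation_fraction`` of cells is held out and scored per epoch.
    ``initial_model`` overrides the default seeded uniform init (used e.g.
    to warm-start or to map a model onto a transposed problem).
    """
    if not expr.is_log2:
        raise ValueError("train expects a log2-preprocessed matrix")
    model = initial_model.copy() if initial_model is not None else init_model(expr, config)
    if [*model.gene_ids] != [*expr.gene_ids] or [*model.sample_ids] != [*expr.sample_ids]:
        raise ValueError("initial_model ids do not match the expression matrix")
    rng = np.random.default_rng([config.seed, 1])
    (si, gi, y), train_cells, val_cells = _holdout_split(expr, config, rng)
    states = (
        _AdamState(model.G.shape),
        _AdamState(model.S.shape),
        _AdamState(model.b_gene.shape[0]),
        _AdamState(model.b_sample.shape[0]),
    )
    report = TrainReport(
        learning_rate=config.learning_rate, epochs=config.epochs, seed=config.seed
    )
    bsz = config.batch_size
    for _ in range(config.epochs):
        order = train_cells[rng.permutation(len(train_cells))]
        sq_sum = 0.0
        for start in range(0, len(order), bsz):
            batch = order[start : start + bsz]
            sq_sum += _sparse_step(
                model, states, si[batch], gi[batch], y[batch], config,
                config.learning_rate,
            )
        report.train_mse.append(sq_sum / len(order))
        if len(val_cells) > 0:
            _, _, pred = _batch_forward(model, si[val_cells], gi[val_cells])
            report.val_mse.append(float(np.mean((pred - y[val_cells]) ** 2)))
    report.epochs = config.epochs
    return model, report


def heldout_mse(
    expr: ExpressionMatrix, config: EmbeddingConfig,
) -> tuple[float, EmbeddingModel, TrainReport]:
    """Convenience: train and return the final held-out-cell MSE."""
    if config.validation_fraction <= 0:
        raise ValueError("heldout_mse needs validation_fraction > 0")
    model, report = train(expr, config)
    return report.val_mse[-1], model, report


def lr_find(
    expr: ExpressionMatrix,
    config: EmbeddingConfig,
    lr_min: float = 1e-5,
    lr_max: float = 1.0,
    steps: int = 100,
) -> LRFindResult:
    """Learning-rate range test: one pass of at most ``steps`` mini-batches
    with geometrically increasing rate, recording the (smoothed) batch loss.

    Suggests the rate one order of magnitude below the loss-minimum rate.
    Truncates with ``diverged=True`` when the loss blows up.
    """
    if not (0 < lr_min < lr_max):
        raise ValueError("need 0 < lr_min < lr_max")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    model = init_model(expr, config)
    rng = np.random.default_rng([config.seed, 1])
    (si, gi, y), train_cells, _ = _holdout_split(expr, config, rng)
    order = train_cells[rng.permutation(len(train_cells))]
    rates = np.geomspace(lr_min, lr_max, steps)
    states = (
        _AdamState(model.G.shape),
        _AdamState(model.S.shape),
        _AdamState(model.b_gene.shape[0]),
        _AdamState(model.b_sample.shape[0]),
    )
    bsz = config.batch_size
    losses: list[float] = []
    smoothed: list[float] = []
    ema = 0.0
    beta = 0.9
    diverged = False
    for step, lr in enumerate(rates):
        start = (step * bsz) % max(len(order) - bsz, 1)
        batch = order[start : start + bsz]
        try:
            sq = _sparse_step(model, states, si[batch], gi[batch], y[batch], config, lr)
        except FloatingPointError:
            diverged = True
            break
        loss = sq / len(batch)
        ema = beta * ema + (1 - beta) * loss
        sm = ema / (1 - beta ** (len(losses) + 1))
        losses.append(loss)
        smoothed.append(sm)
        if len(smoothed) > 10 and sm > 4.0 * min(smoothed):
            diverged = True
            break
    if diverged and len(losses) < 10:
        warnings.warn("loss diverged within the first 10 steps; curve truncated")
    arr_l = np.array(losses)
    arr_s = np.array(smoothed)
    best = int(np.argmin(arr_s)) if len(arr_s) else 0
    suggested = float(rates[best] / 10.0) if len(arr_s) else lr_min
    return LRFindResult(
        rates=rates[: len(arr_l)],
        losses=arr_l,
        smoothed_losses=arr_s,
        suggested_lr=suggested,
        diverged=diverged,
    )


# ---------------------------------------------------------------------------
# serialization

def save_model(
    model: EmbeddingModel, dirpath: str | Path, report: TrainReport | None = None
) -> None:
    """Serialize a model to a directory of TSV files plus a JSON config."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    m = model.dim
    cols = [f"d{j}" for j in range(m)]
    write_matrix_tsv(model.G, model.gene_ids, cols, d / "gene_vectors.tsv", "gene_id")
    write_matrix_tsv(
        model.S, model.sample_ids, cols, d / "sample_vectors.tsv", "sample_id"
    )
    with open(d / "biases.tsv", "w") as fh:
        fh.write("entity_id\tspace\tbias\n")
        for gid, b in zip(model.gene_ids, model.b_gene):
            fh.write(f"{gid}\tgene\t{_FLOAT_FMT % b}\n")
        for sid, b in zip(model.sample_ids, model.b_sample):
            fh.write(f"{sid}\tsample\t{_FLOAT_FMT % b}\n")
    meta = {"config": dataclasses.asdict(model.config)}
    if report is not None:
        meta["train_report"] = dataclasses.asdict(report)
    with open(d / "config.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_vectors(path: Path) -> tuple[list[str], np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def load_model(dirpath: str | Path) -> EmbeddingModel:
    import pandas as pd

    d = Path(dirpath)
    with open(d / "config.json") as fh:
        meta = json.load(fh)
    config = EmbeddingConfig(**meta["config"])
    gene_ids, G = _read_vectors(d / "gene_vectors.tsv")
    sample_ids, S = _read_vectors(d / "sample_vectors.tsv")
    bias_df = pd.read_csv(d / "biases.tsv", sep="\t", float_precision="round_trip")
    gmap = dict(
        zip(
            bias_df[bias_df["space"] == "gene"]["entity_id"].astype(str),
            bias_df[bias_df["space"] == "gene"]["bias"].astype(float),
        )
    )
    smap = dict(
        zip(
            bias_df[bias_df["space"] == "sample"]["entity_id"].astype(str),
            bias_df[bias_df["space"] == "sample"]["bias"].astype(float),
        )
    )
    return EmbeddingModel(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        G=G,
        S=S,
        b_gene=np.array([gmap[g] for g in gene_ids]),
        b_sample=np.array([smap[s] for s in sample_ids]),
        config=config,
    )


def export_projector(
    model: EmbeddingModel,
    dirpath: str | Path,
    space: str = "gene",
    labels: dict[str, str] | None = None,
) -> None:
    """Write TensorBoard-projector-compatible TSVs: vectors without header
    plus a metadata file of entity ids (and optional labels)."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    ids = model.entity_ids(space)
    mat = model.entity_matrix(space)
    with open(d / f"{space}_vectors.tsv", "w") as fh:
        for row in mat:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")
    with open(d / f"{space}_metadata.tsv", "w") as fh:
        if labels is not None:
            fh.write("id\tlabel\n")
            for eid in ids:
                fh.write(f"{eid}\t{labels.get(eid, '')}\n")
        else:
            for eid in ids:
                fh.write(eid + "\n")
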