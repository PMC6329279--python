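"""Reading, preprocessing and writing of expression tables.

The supported dialect is the GDAC RSEM export layout: a tab-separated
numeric table with one header row and one identifier column, genes as rows
by default (an ``orientation`` flag accepts the transposed layout).
Identifiers may be plain symbols or composite ``SYMBOL|ENTREZ`` strings, in
which case the symbol is kept as the gene id and the Entrez part as
metadata; ids that would collide after resolution (or unknown symbols such
as ``?``) retain the full composite string.

Preprocessing follows the RSEM convention for noise suppression: counts
below 1 are floored at 1 and the table is log2-transformed, so a value of
0 after preprocessing means "at or below the noise floor".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "read_expression_table",
    "read_annotations",
    "preprocess",
    "filter_samples",
    "write_expression_table",
    "write_matrix_tsv",
]

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


@dataclass
class ExpressionMatrix:
    """Samples x genes expression matrix with ordered identifiers.

    ``values`` has shape (n_samples, n_genes). ``is_log2`` marks whether
    the values are log2(normalized count floored at 1); raw tables carry
    ``is_log2=False``.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    is_log2: bool = False
    gene_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = len(self.sample_ids), len(self.gene_ids)
        if self.values.shape != (n, k):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {k} genes"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name} ids: {dupes}")
        if self.is_log2:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("log2 matrix contains non-finite values")
            if np.any(self.values < 0):
                raise ValueError("log2 matrix contains negative values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.gene_ids
        )


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample annotation: group label and TCGA-style sample type code.

    Codes whose first character is "1" denote normal (non-tumor) samples.
    """

    sample_id: str
    group_label: str
    sample_type_code: str | None = None

    @property
    def is_normal(self) -> bool:
        return (
            self.sample_type_code is not None
            and len(self.sample_type_code) > 0
            and self.sample_type_code[0] == "1"
        )


def _resolve_composite_ids(raw_ids: Sequence[str]) -> tuple[list[str], dict[str, str]]:
    """Resolve "SYMBOL|ENTREZ" ids to symbols, keeping the full composite
    for unknown symbols ("?") and for symbols that would collide."""
    symbols = []
    for rid in raw_ids:
        sym = rid.split("|", 1)[0] if "|" in rid else rid
        symbols.append(sym)
    counts: dict[str, int] = {}
    for sym in symbols:
        counts[sym] = counts.get(sym, 0) + 1
    resolved: list[str] = []
    meta: dict[str, str] = {}
    for rid, sym in zip(raw_ids, symbols):
        if sym == "?" or sym == "" or counts[sym] > 1:
            resolved.append(rid)
        else:
            resolved.append(sym)
            if "|" in rid:
                meta[sym] = rid.split("|", 1)[1]
    return resolved, meta


def _parse_numeric(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        missing = df[col].isna()
        if bad.any():
            row = df.index[int(np.argmax(bad.to_numpy()))]
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} "
                f"at row {row!r}, column {col!r}"
            )
        if missing.any():
            row = df.index[int(np.argmax(missing.to_numpy()))]
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        out[:, j] = converted.to_numpy(dtype=float)
    return out


def read_expression_table(
    path: str | Path,
    orientation: str = "genes_as_rows",
    id_style: str = "plain",
    is_log2: bool = False,
) -> ExpressionMatrix:
    """Read a tab-separated expression table into an ExpressionMatrix.

    Parameters
    ----------
    path
        TSV file with one header row and one identifier column.
    orientation
        ``genes_as_rows`` (GDAC RSEM layout) or ``samples_as_rows``.
    id_style
        ``plain`` or ``pipe_composite`` (``SYMBOL|ENTREZ`` gene ids).
    is_log2
        Set when the file already holds preprocessed log2 values (e.g. a
        table written by :func:`write_expression_table`); raw tables are
        the default.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if id_style not in ("plain", "pipe_composite"):
        raise ValueError(f"unknown id_style: {id_style!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    values = _parse_numeric(df, path)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "genes_as_rows":
        gene_raw, sample_ids = row_ids, col_ids
        values = values.T
    else:
        gene_raw, sample_ids = col_ids, row_ids
    meta: dict[str, str] = {}
    if id_style == "pipe_composite":
        gene_ids, meta = _resolve_composite_ids(gene_raw)
    else:
        gene_ids = list(gene_raw)
    dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate gene identifiers: {dupes}")
    return ExpressionMatrix(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        values=values,
        is_log2=is_log2,
        gene_meta=meta,
    )


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a TSV annotation file with columns sample_id, group_label and
    optionally sample_type_code."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation file needs columns {sorted(required)}")
    anns = []
    for _, row in df.iterrows():
        code = row.get("sample_type_code")
        if code is not None and (pd.isna(code) or code == ""):
            code = None
        anns.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                group_label=str(row["group_label"]),
                sample_type_code=None if code is None else str(code),
            )
        )
    return anns


def preprocess(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Floor values at 1 and log2-transform.

    Counts below 1 are treated as noise and replaced with 1, so the output
    is 0 exactly where the input was at or below 1.
    """
    if raw.is_log2:
        raise ValueError("matrix is already log2-transformed")
    if np.any(raw.values < 0):
        raise ValueError("negative expression value: cannot be a count")
    values = np.log2(np.maximum(raw.values, 1.0))
    return ExpressionMatrix(
        sample_ids=list(raw.sample_ids),
        gene_ids=list(raw.gene_ids),
        values=values,
        is_log2=True,
        gene_meta=dict(raw.gene_meta),
    )


def filter_samples(
    expr: ExpressionMatrix,
    annotations: Iterable[SampleAnnotation],
    keep: Callable[[SampleAnnotation], bool],
) -> ExpressionMatrix:
    """Row-subset the matrix to annotated samples satisfying ``keep``.

    Samples without an annotation are retained (the predicate only acts on
    annotated samples). Annotations referencing unknown sample ids are
    skipped with a warning. An empty result is an error.
    """
    known = set(expr.sample_ids)
    by_id: dict[str, SampleAnnotation] = {}
    for ann in annotations:
        if ann.sample_id not in known:
            warnings.warn(
                f"annotation references unknown sample id {ann.sample_id!r}; skipped",
                stacklevel=2,
            )
            continue
        by_id[ann.sample_id] = ann
    keep_rows = [
        i
        for i, sid in enumerate(expr.sample_ids)
        if sid not in by_id or keep(by_id[sid])
    ]
    if not keep_rows:
        raise ValueError("sample filter removed every sample")
    return ExpressionMatrix(
        sample_ids=[expr.sample_ids[i] for i in keep_rows],
        gene_ids=list(expr.gene_ids),
        values=expr.values[keep_rows, :],
        is_log2=expr.is_log2,
        gene_meta=dict(expr.gene_meta),
    )


def write_matrix_tsv(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
    index_name: str = "id",
) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if len(row_ids) == 0 or len(col_ids) == 0:
        raise ValueError("refusing to write an empty matrix")
    if matrix.shape != (len(row_ids), len(col_ids)):
        raise ValueError("matrix shape does not match id lists")
    with open(path, "w") as fh:
        fh.write(index_name + "\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, matrix):
            fh.write(rid + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def write_expression_table(
    expr: ExpressionMatrix,
    path: str | Path,
    orientation: str = "genes_as_rows",
) -> None:
    """Write an ExpressionMatrix as TSV; round-trips through
    :func:`read_expression_table` to within 1e-12 relative tolerance."""
    if expr.n_genes == 0 or expr.n_samples == 0:
        raise ValueError("refusing to write an empty expression matrix")
    if orientation == "genes_as_rows":
        write_matrix_tsv(
            expr.values.T, expr.gene_ids, expr.sample_ids, path, index_name="gene_id"
        )
    elif orientation == "samples_as_rows":
        write_matrix_tsv(
            expr.values, expr.sample_ids, expr.gene_ids, path, index_name="sample_id"
        )
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
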