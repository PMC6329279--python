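"""Over-representation analysis of gene lists against gene-set collections.

One-sided Fisher (hypergeometric upper-tail) p-values with
Benjamini-Hochberg FDR; a set is called significantly enriched when
p < 0.01 and FDR < 0.05. Collections are read from and written to the
standard GMT format (term, description, member genes, tab-separated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "read_gmt",
    "write_gmt",
    "bh_fdr",
    "fisher_enrichment",
]

P_THRESHOLD = 0.01
FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping term_id -> (term_name, member gene ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {tid!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {tid!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.sets

    def members(self, term_id: str) -> tuple[str, ...]:
        return self.sets[term_id][1]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p_value: float
    fdr: float
    significant: bool


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">= 1 member"
                )
            term, desc, members = parts[0], parts[1], tuple(p for p in parts[2:] if p)
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, members)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR: q_i = min_{j>=i} p_(j) * T / j,
    clipped to 1, returned in the original order."""
    p = np.asarray(p_values, dtype=float)
    t = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * t / np.arange(1, t + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(t)
    q[order] = q_sorted
    return q


def fisher_enrichment(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Test each gene set for over-representation in ``gene_list``.

    Sets are intersected with the universe before testing; sets with no
    member in the universe are skipped with a warning. The p-value is the
    hypergeometric upper tail P(X >= overlap) with population =
    universe_size, successes = set_size, draws = list_size. BH FDR is
    computed across all tested sets; rows come back sorted by (p, term).
    """
    uni = list(dict.fromkeys(universe))
    lst = list(dict.fromkeys(gene_list))
    if not uni:
        raise ValueError("empty universe")
    if not lst:
        raise ValueError("empty gene list")
    uni_set = set(uni)
    extra = [g for g in lst if g not in uni_set]
    if extra:
        raise ValueError(f"gene list members missing from universe: {sorted(extra)[:5]}")
    lst_set = set(lst)
    u_size, l_size = len(uni_set), len(lst_set)
    tested: list[tuple[str, str, int, int]] = []
    for term in sorted(collection.sets):
        name, members = collection.sets[term]
        in_uni = uni_set.intersection(members)
        if not in_uni:
            warnings.warn(f"gene set {term!r} has no member in the universe; skipped")
            continue
        overlap = len(lst_set.intersection(in_uni))
        tested.append((term, name, overlap, len(in_uni)))
    if not tested:
        return []
    pvals = np.array(
        [hypergeom.sf(ov - 1, u_size, k_set, l_size) for _, _, ov, k_set in tested]
    )
    pvals = np.clip(pvals, 0.0, 1.0)
    fdrs = bh_fdr(pvals)
    rows = [
        EnrichmentRow(
            term_id=term,
            term_name=name,
            overlap=ov,
            list_size=l_size,
            set_size=k_set,
            universe_size=u_size,
            p_value=float(p),
            fdr=float(q),
            significant=bool(p < P_THRESHOLD and q < FDR_THRESHOLD),
        )
        for (term, name, ov, k_set), p, q in zip(tested, pvals, fdrs)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows
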