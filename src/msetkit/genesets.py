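"""Curated gene-set handling: GMT I/O, background restriction, pooling, overlap.

Gene symbols are compared case-insensitively throughout (databases mix human
and mouse casing, e.g. ``PER1`` vs ``Per1``): every symbol is uppercased and
whitespace-trimmed on entry, and all set algebra happens on the normalized
form.

Two pooled databases mirror a common curation strategy for multi-source
disease gene lists: the union of all sources, and the subset of genes backed
by at least *k* independent sources (``k = 2`` being the usual "appears in
two or more lists" criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import GmtParseError, InvalidInputError

__all__ = [
    "normalize_symbol",
    "normalize_symbols",
    "GeneSet",
    "DatabaseCollection",
    "OverlapStats",
    "read_gmt",
    "write_gmt",
    "restrict_to_background",
    "pool_union",
    "pool_min_membership",
    "pairwise_overlap",
]


def normalize_symbol(symbol: str) -> str:
    """Uppercase and trim a gene symbol for case-insensitive matching."""
    return symbol.strip().upper()


def normalize_symbols(symbols: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_symbol(s) for s in symbols if s.strip())


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with provenance.

    ``genes`` holds normalized (uppercased, trimmed) symbols; duplicates that
    differ only by case collapse to one member.
    """

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", normalize_symbols(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0


@dataclass
class DatabaseCollection:
    """An ordered collection of gene sets with unique names."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidInputError(f"duplicate gene-set names in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> DatabaseCollection:
    """Read a GMT file (``name<TAB>description<TAB>gene...`` per line).

    Blank lines are skipped.  A line with fewer than two tab-separated fields
    raises :class:`GmtParseError` naming the line number.  Symbols are
    deduplicated case-insensitively.
    """
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GmtParseError(
                    "expected at least name and description fields", lineno
                )
            name, description = fields[0].strip(), fields[1].strip()
            if not name:
                raise GmtParseError("empty set name", lineno)
            sets.append(GeneSet(name=name, genes=frozenset(fields[2:]), source=description))
    return DatabaseCollection(sets)


def write_gmt(collection: DatabaseCollection | Iterable[GeneSet], path: str | Path) -> None:
    """Write a collection as GMT; genes sorted for reproducible output."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fields = [gs.name, gs.source or "na", *sorted(gs.genes)]
            fh.write("\t".join(fields) + "\n")


def restrict_to_background(gene_set: GeneSet, background: Iterable[str]) -> GeneSet:
    """Intersect a gene set with a measurement background.

    Enrichment statistics are only meaningful when the observed and null
    match counts are taken over the same universe; restriction puts the
    curated list onto the platform's background.  An empty result is allowed
    but flagged with a warning so the enrichment test can refuse it
    explicitly.
    """
    bg = normalize_symbols(background)
    if not bg:
        raise InvalidInputError("background is empty")
    restricted = GeneSet(
        name=f"{gene_set.name}|background",
        genes=gene_set.genes & bg,
        source=gene_set.source,
    )
    if restricted.is_empty:
        warnings.warn(
            f"gene set {gene_set.name!r} has no members on the background",
            stacklevel=2,
        )
    return restricted


def pool_union(collection: DatabaseCollection, name: str = "pooled_union") -> GeneSet:
    """Union of all member sets (all unique genes across sources)."""
    if len(collection) == 0:
        raise InvalidInputError("cannot pool an empty collection")
    genes: set[str] = set()
    for gs in collection:
        genes |= gs.genes
    return GeneSet(name=name, genes=frozenset(genes), source="union of " + ",".join(collection.names))


def pool_min_membership(
    collection: DatabaseCollection, k: int, name: str | None = None
) -> GeneSet:
    """Genes present in at least ``k`` member sets; ``k = 1`` equals the union."""
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    if k > len(collection):
        warnings.warn(
            f"k={k} exceeds collection size {len(collection)}; result is empty",
            stacklevel=2,
        )
    counts: dict[str, int] = {}
    for gs in collection:
        for g in gs.genes:
            counts[g] = counts.get(g, 0) + 1
    genes = frozenset(g for g, c in counts.items() if c >= k)
    return GeneSet(
        name=name or f"pooled_min{k}",
        genes=genes,
        source=f">= {k} of " + ",".join(collection.names),
    )


@dataclass(frozen=True)
class OverlapStats:
    """Pairwise overlap between two gene sets.

    ``size_ratio`` (smaller list size / larger list size) and
    ``overlap_coefficient`` (|A∩B| / min sizes) are both reported: published
    overlap figures are sometimes ambiguous between the two readings, so
    neither is privileged.
    """

    name_a: str
    name_b: str
    size_a: int
    size_b: int
    intersection: int
    size_ratio: float
    overlap_coefficient: float
    jaccard: float


def pairwise_overlap(a: GeneSet, b: GeneSet) -> OverlapStats:
    if a.is_empty or b.is_empty:
        raise InvalidInputError("pairwise_overlap requires non-empty sets")
    inter = len(a.genes & b.genes)
    union = len(a.genes | b.genes)
    small, large = min(len(a), len(b)), max(len(a), len(b))
    return OverlapStats(
        name_a=a.name,
        name_b=b.name,
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        size_ratio=small / large,
        overlap_coefficient=inter / small,
        jaccard=inter / union,
    )


def overlap_table(collection: DatabaseCollection):
    """All pairwise overlap statistics as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, a in enumerate(collection):
        for b in collection.sets[i + 1 :]:
            rows.append(pairwise_overlap(a, b).__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "name_a",
            "name_b",
            "size_a",
            "size_b",
            "intersection",
            "size_ratio",
            "overlap_coefficient",
            "jaccard",
        ],
    )
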