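"""Modular Single-set Enrichment Test (MSET).

MSET asks whether a significant gene list contains more members of a curated
gene set than expected by chance.  The null distribution is built by
randomization: repeatedly draw, without replacement, a same-size gene list
from the measurement background (the universe of unique annotated genes on
the platform) and count matches to the database.  The p-value is the
probability of at least as many matches as observed.

Because both the observed and the null counts are taken after restricting
the database to the background, the null is exactly hypergeometric, and an
analytic upper-tail probability is computed alongside the empirical one as
an internal oracle: agreement of the two is a sharp correctness check on the
sampling machinery.

By default the empirical p uses the standard permutation-test estimator
``(1 + #{null >= observed}) / (1 + R)`` so a p-value of exactly zero is
never reported; the plain ``#{null >= observed} / R`` rule is available via
:class:`MsetConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import substream
from .diffexpr import SignificantSet
from .errors import InvalidInputError
from .genesets import (
    DatabaseCollection,
    GeneSet,
    normalize_symbols,
    restrict_to_background,
)

__all__ = [
    "MsetConfig",
    "MsetResult",
    "count_matches",
    "hypergeom_upper_tail",
    "mset_test",
    "mset_batch",
    "match_report",
]


@dataclass(frozen=True)
class MsetConfig:
    """Randomization settings.

    ``n_randomizations`` defaults to 10,000 draws.  With
    ``pseudocount_correction`` on (default) the reported p is
    ``(1 + #{null >= x}) / (1 + R)``; off gives the plain ``#{>= x} / R``.
    """

    n_randomizations: int = 10_000
    seed: int = 0
    pseudocount_correction: bool = True

    def __post_init__(self):
        if self.n_randomizations < 100:
            raise InvalidInputError(
                f"n_randomizations must be >= 100, got {self.n_randomizations}"
            )


@dataclass
class MsetResult:
    """Outcome of one enrichment test.

    Attributes mirror the sampling scheme: background size ``B``, database
    size on the background ``K``, significant-list size ``n``, observed
    matches ``x``, the full null histogram over 0..min(n, K), the empirical
    p, and the exact hypergeometric upper-tail oracle p.
    """

    database_name: str
    background_size: int
    restricted_db_size: int
    significant_size: int
    observed_matches: int
    null_match_counts: np.ndarray  # histogram, index = match count
    empirical_p: float
    oracle_p: float
    n_randomizations: int

    @property
    def null_mean(self) -> float:
        counts = self.null_match_counts
        return float(np.average(np.arange(len(counts)), weights=counts))

    def as_row(self) -> dict:
        return {
            "database": self.database_name,
            "B": self.background_size,
            "K": self.restricted_db_size,
            "n": self.significant_size,
            "x": self.observed_matches,
            "empirical_p": self.empirical_p,
            "oracle_p": self.oracle_p,
            "n_randomizations": self.n_randomizations,
        }


def count_matches(genes: Iterable[str], database: GeneSet) -> int:
    """Number of genes shared between a list and a database (case-folded)."""
    return len(normalize_symbols(genes) & database.genes)


def hypergeom_upper_tail(x: int, B: int, K: int, n: int) -> float:
    """Exact P(X >= x) for X ~ Hypergeometric(B, K, n).

    The probability that drawing ``n`` genes without replacement from a
    background of ``B`` containing ``K`` database members yields at least
    ``x`` matches.  This is the analytic limit of the MSET null.
    """
    if not (0 <= K <= B and 0 <= n <= B):
        raise InvalidInputError(f"inconsistent counts: B={B}, K={K}, n={n}")
    if not (0 <= x <= min(n, K)):
        raise InvalidInputError(f"x={x} outside [0, min(n, K)={min(n, K)}]")
    if x == 0:
        return 1.0
    # scipy's sf(x-1) = P(X >= x); computed from log-pmf internally, stable
    return float(stats.hypergeom.sf(x - 1, B, K, n))


def _null_match_counts(
    rng: np.random.Generator, member_mask: np.ndarray, n: int, reps: int
) -> np.ndarray:
    """Match counts for ``reps`` draws of ``n`` from the background.

    Each draw is a uniform n-subset of the background obtained by a partial
    Fisher–Yates selection (Generator.choice without replacement).
    """
    B = member_mask.shape[0]
    counts = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        idx = rng.choice(B, size=n, replace=False)
        counts[r] = int(member_mask[idx].sum())
    return counts


def mset_test(
    significant: SignificantSet | Iterable[str],
    database: GeneSet,
    background: Iterable[str],
    config: MsetConfig | None = None,
) -> MsetResult:
    """Randomization enrichment test of a gene list against one database.

    Significant genes not on the background are dropped with a warning; the
    database is restricted to the background before both the observed and
    the null counting so the two live on the same sample space.
    """
    config = config or MsetConfig()
    sig_genes = significant.genes if isinstance(significant, SignificantSet) else normalize_symbols(significant)
    bg = normalize_symbols(background)
    if not bg:
        raise InvalidInputError("background is empty")

    outside = sig_genes - bg
    if outside:
        warnings.warn(
            f"{len(outside)} significant genes absent from background were dropped",
            stacklevel=2,
        )
        sig_genes = sig_genes & bg

    restricted = restrict_to_background(database, bg)
    if restricted.is_empty:
        raise InvalidInputError(
            f"database {database.name!r} has no genes on the background; refusing to test"
        )

    B, K, n = len(bg), len(restricted), len(sig_genes)
    if n > B:
        raise InvalidInputError(f"significant set size {n} exceeds background {B}")

    x = len(sig_genes & restricted.genes)

    bg_sorted = sorted(bg)
    member_mask = np.fromiter(
        (g in restricted.genes for g in bg_sorted), dtype=bool, count=B
    )
    rng = substream(config.seed, "mset", database.name)
    R = config.n_randomizations
    null_counts = _null_match_counts(rng, member_mask, n, R)

    at_least = int(np.count_nonzero(null_counts >= x))
    if config.pseudocount_correction:
        empirical_p = (1 + at_least) / (1 + R)
    else:
        empirical_p = at_least / R

    hist = np.bincount(null_counts, minlength=min(n, K) + 1)
    return MsetResult(
        database_name=database.name,
        background_size=B,
        restricted_db_size=K,
        significant_size=n,
        observed_matches=x,
        null_match_counts=hist,
        empirical_p=float(empirical_p),
        oracle_p=hypergeom_upper_tail(x, B, K, n),
        n_randomizations=R,
    )


def mset_batch(
    significant: SignificantSet | Iterable[str],
    collection: DatabaseCollection,
    background: Iterable[str],
    config: MsetConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, MsetResult]]:
    """Run :func:`mset_test` against every database in a collection.

    Per-database randomization streams are derived from the master seed and
    the database name, so results do not depend on database order.  A failed
    database is flagged in the summary table (``error`` column) and does not
    abort the batch.

    Returns the summary table and a dict of the full per-database results.
    """
    config = config or MsetConfig()
    rows = []
    results: dict[str, MsetResult] = {}
    for db in collection:
        try:
            res = mset_test(significant, db, background, config)
        except InvalidInputError as exc:
            rows.append({"database": db.name, "error": str(exc)})
            continue
        results[db.name] = res
        rows.append({**res.as_row(), "error": ""})
    cols = ["database", "B", "K", "n", "x", "empirical_p", "oracle_p", "n_randomizations", "error"]
    table = pd.DataFrame(rows)
    for c in cols:
        if c not in table.columns:
            table[c] = np.nan
    return table[cols], results


def match_report(
    significant: SignificantSet | Iterable[str], collection: DatabaseCollection
) -> pd.DataFrame:
    """Per-gene membership table for significant genes found in >= 1 database.

    Rows are genes, one boolean column per database, plus ``n_databases``
    (supporting the "appears in two or more lists" pooling criterion).
    """
    sig_genes = significant.genes if isinstance(significant, SignificantSet) else normalize_symbols(significant)
    rows = {}
    for g in sorted(sig_genes):
        flags = {db.name: g in db.genes for db in collection}
        if any(flags.values()):
            rows[g] = flags
    report = pd.DataFrame.from_dict(rows, orient="index", columns=collection.names)
    if report.empty:
        report = pd.DataFrame(columns=[*collection.names, "n_databases"])
        report.index.name = "gene"
        return report
    report = report.astype(bool)
    report["n_databases"] = report.sum(axis=1)
    report.index.name = "gene"
    return report
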