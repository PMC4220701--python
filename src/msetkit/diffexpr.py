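"""Two-group differential expression on log2-scale normalized intensities.

The test statistic is an ordinary two-sample pooled-variance t on log2
values, optionally with empirical-Bayes variance moderation: each gene's
pooled variance is shrunk toward a prior (the trimmed mean of all gene
variances) with a configurable prior degrees of freedom, and the t statistic
is referred to a t distribution with the augmented degrees of freedom.  At
small group sizes (six arrays per group is typical for this design) the
moderated test behaves like limma's moderated t without reproducing its
exact empirical-Bayes internals; moderation is switchable.

Fold change is the ratio of linear-scale group means under the log model:
``2 ** (mean log2 group A − mean log2 group B)``, so > 1 means higher in
group A.  P-values are nominal — no multiple-testing adjustment is applied;
downstream enrichment testing operates on nominal-cutoff significant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from scipy.special import digamma, polygamma

from .errors import InvalidDesignError, InvalidInputError
from .genesets import normalize_symbol

__all__ = [
    "ExpressionMatrix",
    "DifferentialResults",
    "SignificantSet",
    "fit_two_group",
    "collapse_probes",
    "significant_set",
    "read_expression_tsv",
    "write_expression_tsv",
]

# variance floor: keeps the t statistic finite for constant genes while the
# equal-mean case still yields t = 0, p = 1
_VAR_FLOOR = 1e-8


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2-scale intensities with group labels.

    ``values`` is a DataFrame indexed by unique (case-folded-unique) gene or
    probe identifiers, columns are sample ids; ``groups`` maps each sample id
    to one of two group names.
    """

    values: pd.DataFrame
    groups: pd.Series  # sample_id -> group label

    def __post_init__(self):
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups)
        if self.values.isna().any().any():
            raise InvalidInputError("expression matrix contains missing values")
        if not self.values.columns.equals(pd.Index(self.groups.index)):
            # allow any ordering of the sample sheet
            missing = set(self.values.columns) - set(self.groups.index)
            if missing:
                raise InvalidInputError(f"samples without group labels: {sorted(missing)}")
            self.groups = self.groups.loc[self.values.columns]
        folded = self.values.index.astype(str).str.upper()
        if folded.duplicated().any():
            dupes = sorted(set(folded[folded.duplicated()]))
            raise InvalidInputError(f"duplicate gene ids after case-folding: {dupes[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def group_names(self) -> list[str]:
        return list(pd.unique(self.groups))

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class DifferentialResults:
    """Per-gene two-group results.

    ``table`` columns: ``coef_<groupA>``, ``coef_<groupB>`` (group mean log2
    expression), ``fold_change`` (linear A/B ratio), ``p_value`` (nominal,
    two-sided).  ``group_a`` is the numerator group of the fold change.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"]

    @property
    def fold_changes(self) -> pd.Series:
        return self.table["fold_change"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, group_a: str, group_b: str) -> "DifferentialResults":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"), group_a, group_b)


@dataclass(frozen=True)
class SignificantSet:
    """Genes with nominal p strictly below ``alpha``."""

    alpha: float
    genes: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.genes)


def _estimate_prior(pooled_var: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Moment-based empirical-Bayes prior (s0^2, d0) for gene variances.

    Under the scaled inverse-chi-square prior the marginal distribution of
    each log sample variance has excess spread trigamma(d0/2) beyond the
    trigamma(d/2) sampling term; inverting that relation yields the prior
    degrees of freedom, and the prior variance follows from the mean.  When
    the observed spread does not exceed the sampling term (homogeneous true
    variances) the prior df is effectively infinite and moderation reduces
    to replacing each variance by the common one.
    """
    z = np.log(np.maximum(pooled_var, _VAR_FLOOR))
    d2 = df_resid / 2.0
    e = z - digamma(d2) + np.log(d2)
    excess = float(np.var(e, ddof=1)) - float(polygamma(1, d2))
    if excess <= 1.0 / _D0_CAP:
        d0 = float(_D0_CAP)
    else:
        # invert trigamma(d0/2) = excess by Newton's method
        y = max(0.5 + 1.0 / excess, 1e-2)  # good starting point for trigamma inverse
        for _ in range(50):
            tri = polygamma(1, y)
            delta = tri * (1.0 - tri / excess) / polygamma(2, y)
            y += delta
            if abs(delta) < 1e-10 * y:
                break
        d0 = float(min(2.0 * y, _D0_CAP))
    s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0))) if d0 < _D0_CAP else float(np.exp(np.mean(e)))
    return max(s0_sq, _VAR_FLOOR), d0


_D0_CAP = 1e7  # prior df above this is treated as infinite


def fit_two_group(
    expr: ExpressionMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    moderate: bool = True,
    prior_df: float | str = "auto",
    trim: float = 0.1,
) -> DifferentialResults:
    """Per-gene two-group contrast with optional variance moderation.

    Parameters
    ----------
    group_a, group_b
        Numerator and denominator groups of the fold change.  Default: the
        two groups in order of first appearance in the sample sheet.
    moderate
        Shrink per-gene pooled variances toward a prior variance with
        ``prior_df`` prior degrees of freedom, and refer the statistic to a
        t distribution with the augmented degrees of freedom.
    prior_df
        ``"auto"`` (default) estimates the prior df and prior variance by
        moments from the distribution of gene variances; a number fixes the
        prior df, with the prior variance taken as the trimmed mean of gene
        variances (``trim`` cut from each tail).
    """
    names = expr.group_names
    if len(names) != 2:
        raise InvalidDesignError(f"exactly two groups required, found {names}")
    if group_a is None:
        group_a, group_b = names
    elif group_b is None:
        group_b = next(n for n in names if n != group_a)
    for g in (group_a, group_b):
        if g not in names:
            raise InvalidDesignError(f"group {g!r} not present in sample sheet")

    xa = expr.values[expr.samples_in(group_a)].to_numpy()
    xb = expr.values[expr.samples_in(group_b)].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise InvalidDesignError(
            f"each group needs >= 2 samples (got {group_a}: {na}, {group_b}: {nb})"
        )

    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    df_resid = na + nb - 2
    pooled_var = ((xa.var(axis=1, ddof=1) * (na - 1)) + (xb.var(axis=1, ddof=1) * (nb - 1))) / df_resid
    pooled_var = np.maximum(pooled_var, _VAR_FLOOR)

    if moderate and len(pooled_var) > 1:
        if prior_df == "auto":
            prior_var, d0 = _estimate_prior(pooled_var, df_resid)
        else:
            d0 = float(prior_df)
            prior_var = max(float(stats.trim_mean(pooled_var, proportiontocut=trim)), _VAR_FLOOR)
        if d0 >= _D0_CAP:
            post_var = np.full_like(pooled_var, prior_var)
            df_total = _D0_CAP
        else:
            post_var = (d0 * prior_var + df_resid * pooled_var) / (d0 + df_resid)
            df_total = df_resid + d0
    else:
        post_var = pooled_var
        df_total = df_resid

    se = np.sqrt(post_var * (1.0 / na + 1.0 / nb))
    tstat = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            f"coef_{group_a}": mean_a,
            f"coef_{group_b}": mean_b,
            "fold_change": np.exp2(mean_a - mean_b),
            "p_value": p,
        },
        index=expr.gene_ids,
    )
    return DifferentialResults(table, group_a, group_b)


def collapse_probes(
    results: DifferentialResults, probe_to_gene: Mapping[str, str | None]
) -> DifferentialResults:
    """Collapse probe-level results to gene level.

    Each annotated gene keeps its minimum-p representative probe; probes with
    no annotation (missing key, ``None`` or empty symbol) are dropped.  Gene
    symbols are case-folded on output.
    """
    if not probe_to_gene:
        raise InvalidInputError("probe-to-gene map is empty")
    tab = results.table.copy()
    genes = [
        normalize_symbol(g) if (g := probe_to_gene.get(p)) else None
        for p in tab.index
    ]
    tab["__gene"] = genes
    tab = tab.dropna(subset=["__gene"])
    if tab.empty:
        return DifferentialResults(
            tab.drop(columns="__gene").iloc[0:0], results.group_a, results.group_b
        )
    # representative probe per gene = minimum p-value (stable for ties)
    best = tab.sort_values("p_value", kind="stable").drop_duplicates("__gene")
    best = best.set_index("__gene").sort_index()
    best.index.name = None
    return DifferentialResults(best, results.group_a, results.group_b)


def significant_set(results: DifferentialResults, alpha: float) -> SignificantSet:
    """Symbols with nominal p strictly below ``alpha``."""
    if not (0 < alpha <= 1):
        raise InvalidInputError(f"alpha must be in (0, 1], got {alpha}")
    mask = results.table["p_value"] < alpha
    genes = frozenset(normalize_symbol(str(g)) for g in results.table.index[mask])
    return SignificantSet(alpha=alpha, genes=genes)


def read_expression_tsv(expr_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene, rest samples) + sample sheet."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index.name = None
    sheet = pd.read_csv(samples_path, sep="\t")
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise InvalidInputError("sample sheet needs columns sample_id, group")
    groups = sheet.set_index("sample_id")["group"]
    return ExpressionMatrix(values, groups)


def write_expression_tsv(
    expr: ExpressionMatrix, expr_path: str | Path, samples_path: str | Path
) -> None:
    expr.values.to_csv(expr_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample_id": expr.groups.index, "group": expr.groups.values}
    ).to_csv(samples_path, sep="\t", index=False)
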