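"""Relative-expression qPCR confirmation with efficiency-aware normalization.

The quantification cycle Cq is the PCR cycle at which fluorescence crosses
threshold; one cycle fewer means roughly one doubling more template.  The
ratio of target expression between two groups, normalized to reference
genes, follows the efficiency-corrected model:

    ratio = E_t ** dCq_t / geometric-mean over refs of (E_r ** dCq_r)

where ``dCq = mean Cq(group_b) − mean Cq(group_a)`` and E is the per-gene
amplification efficiency (2.0 = perfect doubling).  A ratio above 1 means
the target is more highly expressed in ``group_a``.  Two stable reference
genes combined by geometric mean is the standard multi-reference extension
of this model.

Significance comes from a randomization test: group labels are permuted
across samples, the log-ratio recomputed each iteration, and the two-sided
p is the pseudocount-corrected fraction of permutations whose |log ratio|
is at least the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import substream
from .errors import InvalidDesignError, InvalidInputError

__all__ = [
    "CqTable",
    "RelativeExpression",
    "relative_expression",
    "randomization_test",
    "analyze_qpcr",
]

DEFAULT_EFFICIENCY = 2.0


@dataclass
class CqTable:
    """Long-format Cq measurements: one row per (sample, gene).

    ``data`` columns: sample_id, group, gene, cq.  ``efficiencies`` maps gene
    to amplification efficiency in (1, 2]; genes absent from the map use the
    perfect-doubling default of 2.0.
    """

    data: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        required = {"sample_id", "group", "gene", "cq"}
        if not required <= set(self.data.columns):
            raise InvalidInputError(f"Cq table needs columns {sorted(required)}")
        for gene, eff in self.efficiencies.items():
            if not (1.0 < eff <= 2.0):
                raise InvalidInputError(f"efficiency for {gene} must be in (1, 2], got {eff}")

    def efficiency(self, gene: str) -> float:
        return self.efficiencies.get(gene, DEFAULT_EFFICIENCY)

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene"]))

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, efficiencies: Mapping[str, float] | None = None
    ) -> "CqTable":
        return cls(pd.read_csv(path, sep="\t"), dict(efficiencies or {}))


@dataclass(frozen=True)
class RelativeExpression:
    """Efficiency-corrected group ratio for one target gene."""

    gene: str
    ratio: float
    p_value: float
    n_iterations: int


class _RatioMachine:
    """Pivoted Cq matrix with fast log-ratio evaluation over sample subsets.

    Rows: [target, *refs]; columns: samples_a followed by samples_b.  The
    log-ratio for any relabeling is a weighted difference of row means, so
    permutation iterations reduce to cheap numpy indexing.
    """

    def __init__(
        self,
        cq: CqTable,
        target: str,
        refs: Sequence[str],
        samples_a: Sequence[str],
        samples_b: Sequence[str],
    ):
        genes = [target, *refs]
        samples = [*samples_a, *samples_b]
        pivot = cq.data.pivot_table(index="gene", columns="sample_id", values="cq", aggfunc="mean")
        for g in genes:
            if g not in pivot.index:
                raise InvalidInputError(f"gene {g!r} absent from Cq table")
            missing = [s for s in samples if s not in pivot.columns or pd.isna(pivot.loc[g, s])]
            if missing:
                raise InvalidInputError(
                    f"missing Cq for gene {g!r} in samples {missing[:5]}"
                )
        self.matrix = pivot.loc[genes, samples].to_numpy(dtype=float)
        self.log_e = np.array([math.log(cq.efficiency(g)) for g in genes])
        self.n_a = len(samples_a)
        self.n_total = len(samples)

    def log_ratio(self, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        d_cq = self.matrix[:, idx_b].mean(axis=1) - self.matrix[:, idx_a].mean(axis=1)
        contrib = d_cq * self.log_e
        return float(contrib[0] - contrib[1:].mean())


def _group_samples(cq: CqTable, group_a: str, group_b: str) -> tuple[list[str], list[str]]:
    data = cq.data
    sample_groups = data[["sample_id", "group"]].drop_duplicates().set_index("sample_id")["group"]
    samples_a = list(sample_groups.index[sample_groups == group_a])
    samples_b = list(sample_groups.index[sample_groups == group_b])
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise InvalidDesignError(
            f"each group needs >= 2 samples ({group_a}: {len(samples_a)}, {group_b}: {len(samples_b)})"
        )
    return samples_a, samples_b


def relative_expression(
    cq: CqTable,
    target: str,
    refs: Sequence[str],
    group_a: str,
    group_b: str,
) -> float:
    """Efficiency-corrected expression ratio of ``target``, group_a / group_b."""
    if not refs:
        raise InvalidInputError("at least one reference gene required")
    samples_a, samples_b = _group_samples(cq, group_a, group_b)
    machine = _RatioMachine(cq, target, refs, samples_a, samples_b)
    idx_a = np.arange(machine.n_a)
    idx_b = np.arange(machine.n_a, machine.n_total)
    return math.exp(machine.log_ratio(idx_a, idx_b))


def randomization_test(
    cq: CqTable,
    target: str,
    refs: Sequence[str],
    group_a: str,
    group_b: str,
    iterations: int = 2000,
    seed: int = 0,
) -> RelativeExpression:
    """Two-sided permutation test of the normalized expression ratio.

    Sample-level group labels are permuted jointly across all genes (each
    sample keeps its full Cq profile), preserving within-sample gene
    covariance under the null of no group difference.
    """
    if iterations < 1000:
        raise InvalidInputError(f"iterations must be >= 1000, got {iterations}")
    if not refs:
        raise InvalidInputError("at least one reference gene required")
    samples_a, samples_b = _group_samples(cq, group_a, group_b)
    # canonical sample order: the null stream does not depend on which group
    # is the numerator, so swapping groups preserves the p-value exactly
    ordered = sorted([*samples_a, *samples_b])
    machine = _RatioMachine(cq, target, refs, ordered[: len(samples_a)], ordered[len(samples_a):])
    pos = {s: i for i, s in enumerate(ordered)}
    idx_a = np.array([pos[s] for s in samples_a])
    idx_b = np.array([pos[s] for s in samples_b])
    observed = machine.log_ratio(idx_a, idx_b)

    rng = substream(seed, "qpcr", target)
    exceed = 0
    for _ in range(iterations):
        perm = rng.permutation(machine.n_total)
        null = machine.log_ratio(perm[: machine.n_a], perm[machine.n_a :])
        if abs(null) >= abs(observed) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + iterations)
    return RelativeExpression(
        gene=target, ratio=math.exp(observed), p_value=float(p), n_iterations=iterations
    )


def analyze_qpcr(
    cq: CqTable,
    targets: Sequence[str],
    refs: Sequence[str],
    group_a: str,
    group_b: str,
    iterations: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratio + randomization p for each target; TSV-ready table."""
    rows = []
    for gene in targets:
        res = randomization_test(cq, gene, refs, group_a, group_b, iterations, seed)
        rows.append(
            {"gene": res.gene, "ratio": res.ratio, "p_value": res.p_value, "n_iterations": res.n_iterations}
        )
    return pd.DataFrame(rows, columns=["gene", "ratio", "p_value", "n_iterations"])
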