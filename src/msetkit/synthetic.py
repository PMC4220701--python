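"""Synthetic pipeline inputs with known ground truth.

Every downstream stage — two-group differential expression, randomization
enrichment, coexpression module detection and qPCR confirmation — is
exercised on data from these generators, so the whole pipeline is testable
without any external download.  Each generator plants a known truth (which
genes are differentially expressed, which gene sets are enriched, which
genes form modules, what the true expression ratios are) and returns it
alongside the data.

The statistical shape emulates a small two-group microarray study of brain
tissue: six arrays per group, log2-scale intensities with Gaussian noise
(log-normal on the linear scale — the standard microarray error model),
curated disease gene lists of a few hundred genes with controllable mutual
overlap, latent-factor coexpression modules, and ten qPCR samples per group
normalized to reference genes.

All draws flow from the spec's seed through named substreams, so identical
specs yield bit-identical outputs regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import substream
from .diffexpr import ExpressionMatrix
from .errors import InvalidSpecError
from .genesets import DatabaseCollection, GeneSet
from .qpcr import CqTable

__all__ = [
    "UniverseSpec",
    "DeSpec",
    "GenesetSpec",
    "ModuleSpec",
    "QpcrSpec",
    "Universe",
    "simulate_universe",
    "simulate_expression",
    "simulate_genesets",
    "simulate_modules",
    "simulate_qpcr",
]

GROUP_A = "postpartum"
GROUP_B = "virgin"


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class UniverseSpec:
    """The measurement background: unique gene symbols, some flagged as TFs."""

    n_genes: int
    n_tf: int = 0
    symbol_prefix: str = "GENE"
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise InvalidSpecError(f"n_genes must be >= 1, got {self.n_genes}")
        if not (0 <= self.n_tf <= self.n_genes):
            raise InvalidSpecError(
                f"n_tf must be in [0, n_genes={self.n_genes}], got {self.n_tf}"
            )


@dataclass(frozen=True)
class DeSpec:
    """Two-group expression design with planted differential expression.

    ``effect_log2`` is the absolute log2 group-mean shift carried by each of
    the ``n_de`` planted genes; ``direction_prob_up`` is the probability a
    planted gene is shifted up in the first (postpartum) group.
    """

    n_per_group: int = 6
    n_de: int = 0
    effect_log2: float = 1.0
    noise_sd_log2: float = 0.25
    direction_prob_up: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise InvalidSpecError("n_per_group must be >= 2")
        if self.n_de < 0:
            raise InvalidSpecError("n_de must be >= 0")
        if self.noise_sd_log2 <= 0:
            raise InvalidSpecError("noise_sd_log2 must be > 0")
        if not (0 <= self.direction_prob_up <= 1):
            raise InvalidSpecError("direction_prob_up must be in [0, 1]")


@dataclass(frozen=True)
class GenesetSpec:
    """Curated-database shapes: set sizes, planted enrichment, shared core.

    ``enrichment_fraction`` is the fraction of each set drawn from the
    planted differentially-expressed genes; ``shared_core_size`` symbols are
    common to all generated sets (controlling mutual overlap between
    databases, as curated disease lists typically share a core of
    well-studied genes).
    """

    sizes: Sequence[int]
    enrichment_fraction: float = 0.0
    shared_core_size: int = 0
    names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.enrichment_fraction <= 1):
            raise InvalidSpecError("enrichment_fraction must be in [0, 1]")
        if self.shared_core_size < 0:
            raise InvalidSpecError("shared_core_size must be >= 0")
        for s in self.sizes:
            if s < self.shared_core_size:
                raise InvalidSpecError(
                    f"set size {s} smaller than shared_core_size {self.shared_core_size}"
                )
        if self.names is not None and len(self.names) != len(self.sizes):
            raise InvalidSpecError("names must match sizes in length")


@dataclass(frozen=True)
class ModuleSpec:
    """Planted coexpression modules via latent eigengene factors.

    Genes in a module are ``loading * latent + sqrt(1 - loading^2) * noise``
    on the standardized scale, so the gene–eigengene correlation is the
    loading and the within-module gene–gene correlation is loading².
    """

    module_sizes: Sequence[int] = ()
    eigengene_loading: float = 0.8
    n_samples: int = 12
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.eigengene_loading < 1):
            raise InvalidSpecError("eigengene_loading must be strictly in (0, 1)")
        if self.n_samples < 3:
            raise InvalidSpecError("n_samples must be >= 3")
        if any(s < 1 for s in self.module_sizes):
            raise InvalidSpecError("module sizes must be positive")


@dataclass(frozen=True)
class QpcrSpec:
    """Cq-table design consistent with planted expression ratios.

    ``target_ratios`` maps each gene to its true postpartum/virgin
    expression ratio; reference genes must be present with ratio exactly 1.
    Cq values satisfy ``E ** (−Cq) ∝ expression``.
    """

    target_ratios: Mapping[str, float]
    reference_genes: Sequence[str] = ("Ywhaz", "Ppia")
    n_per_group: int = 10
    efficiencies: Mapping[str, float] = field(default_factory=dict)
    cq_noise_sd: float = 0.15
    base_cq_range: tuple[float, float] = (20.0, 28.0)
    seed: int = 0

    def __post_init__(self):
        for gene, ratio in self.target_ratios.items():
            if ratio <= 0:
                raise InvalidSpecError(f"ratio for {gene} must be > 0, got {ratio}")
        for ref in self.reference_genes:
            if ref not in self.target_ratios:
                raise InvalidSpecError(f"reference gene {ref!r} missing from target_ratios")
            if self.target_ratios[ref] != 1:
                raise InvalidSpecError(
                    f"reference gene {ref!r} must have ratio exactly 1"
                )
        for gene, eff in self.efficiencies.items():
            if not (1.0 < eff <= 2.0):
                raise InvalidSpecError(f"efficiency for {gene} must be in (1, 2], got {eff}")
        if self.n_per_group < 2:
            raise InvalidSpecError("n_per_group must be >= 2")
        if self.cq_noise_sd < 0:
            raise InvalidSpecError("cq_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# universe


@dataclass(frozen=True)
class Universe:
    """A gene background with transcription-factor flags."""

    symbols: tuple[str, ...]
    tf_symbols: frozenset[str]

    def __len__(self) -> int:
        return len(self.symbols)

    def write(self, genes_path: str | Path, tf_path: str | Path | None = None) -> None:
        Path(genes_path).write_text("\n".join(self.symbols) + "\n")
        if tf_path is not None:
            ordered = [s for s in self.symbols if s in self.tf_symbols]
            Path(tf_path).write_text("\n".join(ordered) + ("\n" if ordered else ""))


def simulate_universe(spec: UniverseSpec) -> Universe:
    """Generate ``n_genes`` unique symbols with ``n_tf`` flagged as TFs.

    Symbols are zero-padded (``GENE00001``, ...), unique after case-folding
    by construction; the TF subset is a uniform draw.
    """
    width = len(str(spec.n_genes))
    symbols = tuple(
        f"{spec.symbol_prefix.upper()}{i + 1:0{width}d}" for i in range(spec.n_genes)
    )
    rng = substream(spec.seed, "universe")
    tf_idx = rng.choice(spec.n_genes, size=spec.n_tf, replace=False)
    return Universe(symbols=symbols, tf_symbols=frozenset(symbols[i] for i in tf_idx))


# ---------------------------------------------------------------------------
# expression with planted differential expression


def simulate_expression(
    universe: Universe, spec: DeSpec
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group log2 expression with ``n_de`` planted group-mean shifts.

    Returns the matrix and a truth table (gene, direction, log2_shift,
    true_ratio) listing exactly the genes whose generating means differ
    between the groups.  Noise is Gaussian on the log2 scale.
    """
    n_genes = len(universe)
    if spec.n_de > n_genes:
        raise InvalidSpecError(f"n_de={spec.n_de} exceeds universe size {n_genes}")

    rng = substream(spec.seed, "expression")
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_genes)

    shifts = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, size=spec.n_de, replace=False)
    signs = np.where(rng.random(spec.n_de) < spec.direction_prob_up, 1.0, -1.0)
    shifts[de_idx] = signs * spec.effect_log2

    n = spec.n_per_group
    noise = rng.normal(0.0, spec.noise_sd_log2, size=(n_genes, 2 * n))
    means = np.column_stack([baseline + shifts] * n + [baseline] * n)
    values = means + noise

    sample_ids = [f"pp_{i + 1}" for i in range(n)] + [f"v_{i + 1}" for i in range(n)]
    groups = pd.Series([GROUP_A] * n + [GROUP_B] * n, index=sample_ids)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(universe.symbols), columns=sample_ids), groups
    )

    order = np.sort(de_idx)
    truth = pd.DataFrame(
        {
            "gene": [universe.symbols[i] for i in order],
            "direction": np.sign(shifts[order]).astype(int),
            "log2_shift": shifts[order],
            "true_ratio": np.exp2(shifts[order]),
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# gene-set databases


def simulate_genesets(
    universe: Universe, truth: pd.DataFrame | Sequence[str], spec: GenesetSpec
) -> DatabaseCollection:
    """Curated-database stand-ins with planted enrichment and a shared core.

    Each set of size K receives a shared core (drawn once, common to all
    sets), then ``round(enrichment_fraction * remaining)`` genes from the
    planted DE list, then uniform fill from the rest of the universe.  With
    ``enrichment_fraction = 0`` and no core, sets are uniform draws.
    """
    symbols = np.array(universe.symbols, dtype=object)
    n_genes = len(symbols)
    de_genes = list(truth["gene"]) if isinstance(truth, pd.DataFrame) else list(truth)
    for s in spec.sizes:
        if s > n_genes:
            raise InvalidSpecError(f"set size {s} exceeds universe size {n_genes}")

    rng = substream(spec.seed, "genesets")
    core = set(
        symbols[rng.choice(n_genes, size=spec.shared_core_size, replace=False)]
    )

    names = list(spec.names) if spec.names else [f"DB{i + 1}" for i in range(len(spec.sizes))]
    sets = []
    for name, size in zip(names, spec.sizes):
        members = set(core)
        remaining = size - len(members)
        n_enriched = int(round(spec.enrichment_fraction * remaining))
        pool_de = [g for g in de_genes if g not in members]
        if n_enriched > len(pool_de):
            raise InvalidSpecError(
                f"set {name!r} needs {n_enriched} planted-DE genes but only "
                f"{len(pool_de)} are available"
            )
        if n_enriched:
            picked = rng.choice(len(pool_de), size=n_enriched, replace=False)
            members |= {pool_de[i] for i in picked}
        # uniform fill from the whole universe so unenriched sets follow the
        # hypergeometric null exactly (DE genes enter at the background rate)
        pool_bg = [g for g in symbols if g not in members]
        n_fill = size - len(members)
        if n_fill > len(pool_bg):
            raise InvalidSpecError(f"cannot fill set {name!r} to size {size}")
        if n_fill:
            picked = rng.choice(len(pool_bg), size=n_fill, replace=False)
            members |= {pool_bg[i] for i in picked}
        sets.append(GeneSet(name=name, genes=frozenset(members), source="synthetic"))
    return DatabaseCollection(sets)


# ---------------------------------------------------------------------------
# coexpression modules


def simulate_modules(
    universe: Universe, spec: ModuleSpec
) -> tuple[ExpressionMatrix, pd.Series]:
    """Latent-factor module expression plus a gene→module truth map.

    Module genes load on a shared latent sample vector with the configured
    loading; all other genes are independent noise.  The truth labels
    modules ``M1``, ``M2``, ... in descending size order and background
    genes ``unassigned``.
    """
    from .coexpression import UNASSIGNED

    n_genes = len(universe)
    total = int(sum(spec.module_sizes))
    if total > n_genes:
        raise InvalidSpecError(
            f"sum of module sizes {total} exceeds universe size {n_genes}"
        )

    rng = substream(spec.seed, "modules")
    n_s = spec.n_samples
    values = rng.normal(0.0, 1.0, size=(n_genes, n_s))

    order = np.argsort([-s for s in spec.module_sizes], kind="stable")
    labels = pd.Series(UNASSIGNED, index=list(universe.symbols), name="module")
    start = 0
    lam = spec.eigengene_loading
    resid = np.sqrt(1.0 - lam**2)
    for rank, m in enumerate(order, start=1):
        size = spec.module_sizes[m]
        latent = rng.normal(0.0, 1.0, size=n_s)
        # standardize across samples so the planted gene-latent correlation
        # equals the nominal loading even at small sample counts
        latent = (latent - latent.mean()) / latent.std()
        block = slice(start, start + size)
        values[block] = lam * latent[None, :] + resid * values[block]
        labels.iloc[block] = f"M{rank}"
        start += size

    values = values + spec.baseline_mean
    sample_ids = [f"s_{i + 1}" for i in range(n_s)]
    half = n_s // 2
    groups = pd.Series(
        [GROUP_A] * half + [GROUP_B] * (n_s - half), index=sample_ids
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(universe.symbols), columns=sample_ids), groups
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(spec: QpcrSpec) -> CqTable:
    """Cq table whose group ΔCq encodes the planted expression ratios.

    For gene g with efficiency E and true postpartum/virgin ratio r, the
    postpartum group's mean Cq sits ``log_E(r)`` cycles below the virgin
    group's (more template → earlier threshold crossing); replicate noise is
    Gaussian with sd ``cq_noise_sd``.
    """
    rng = substream(spec.seed, "qpcr")
    genes = list(spec.target_ratios)
    lo, hi = spec.base_cq_range
    base_cq = {g: float(rng.uniform(lo, hi)) for g in genes}

    n = spec.n_per_group
    samples_a = [f"pp_{i + 1}" for i in range(n)]
    samples_b = [f"v_{i + 1}" for i in range(n)]

    rows = []
    for g in genes:
        eff = spec.efficiencies.get(g, 2.0)
        shift = np.log(spec.target_ratios[g]) / np.log(eff)
        for s in samples_a:
            noise = rng.normal(0.0, spec.cq_noise_sd) if spec.cq_noise_sd > 0 else 0.0
            rows.append((s, GROUP_A, g, base_cq[g] - shift + noise))
        for s in samples_b:
            noise = rng.normal(0.0, spec.cq_noise_sd) if spec.cq_noise_sd > 0 else 0.0
            rows.append((s, GROUP_B, g, base_cq[g] + noise))
    data = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "cq"])
    return CqTable(data=data, efficiencies=dict(spec.efficiencies))
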