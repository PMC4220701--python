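"""Weighted coexpression network modules and transcription-factor subnetworks.

The workflow follows the weighted gene coexpression network analysis (WGCNA)
framework: pairwise Pearson correlations on log2 expression are raised to a
soft-thresholding power β chosen so the weighted network approximates
scale-free topology (model fit R² above a threshold, 0.8 by default);
topological overlap turns the adjacency into a similarity that credits
shared neighbors; average-linkage hierarchical clustering on 1 − TOM yields
candidate modules, filtered by a minimum size (30 genes by default) and a
cohesion check, and merged when their eigengenes (first principal component
of the module expression) are highly correlated (dissimilarity below 0.25 by
default).

The tree is cut at a fixed quantile of the dendrogram merge heights rather
than with the Dynamic Hybrid algorithm: the static cut keeps the procedure
fully specified while honoring the minimum-size and merge parameters.  A
module-cohesion filter (median gene–eigengene correlation) discards chance
clusters that a static cut produces on structureless data.

The transcription-factor subnetwork retains, within each module, the gene
pairs with at least one transcription-factor endpoint, weighted by their
correlation — an edge list importable by Cytoscape as a text network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import ExpressionMatrix
from .errors import InvalidInputError
from .genesets import normalize_symbol, normalize_symbols

__all__ = [
    "CoexpressionConfig",
    "ModuleAssignment",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "tf_subnetwork",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CoexpressionConfig:
    candidate_betas: Sequence[int] = tuple(range(1, 21))
    scale_free_r2_threshold: float = 0.8
    min_module_size: int = 30
    merge_threshold: float = 0.25
    network_type: str = "unsigned"
    n_degree_bins: int = 10
    cut_quantile: float = 0.99
    min_module_cohesion: float = 0.6  # median |cor(gene, eigengene)| to accept a module
    min_mean_connectivity: float = 2.0  # powers that disconnect the network are excluded

    def __post_init__(self):
        if not (0 < self.scale_free_r2_threshold < 1):
            raise InvalidInputError("scale_free_r2_threshold must be in (0,1)")
        if not (0 < self.merge_threshold < 1):
            raise InvalidInputError("merge_threshold must be in (0,1)")
        if self.min_module_size < 2:
            raise InvalidInputError("min_module_size must be >= 2")
        if self.network_type not in ("unsigned", "signed"):
            raise InvalidInputError("network_type must be 'unsigned' or 'signed'")


@dataclass
class ModuleAssignment:
    """Gene-to-module map with eigengenes and the soft-threshold fit table.

    ``labels`` maps each gene to ``"M1"``, ``"M2"``, ... (descending size) or
    :data:`UNASSIGNED`.  ``eigengenes`` has one unit-norm column per module
    over samples, sign-oriented to correlate positively with the module's
    mean expression profile.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    chosen_beta: int
    scale_free_fit_table: pd.DataFrame

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.labels[self.labels != UNASSIGNED]
        return assigned.value_counts()

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _drop_constant_rows(values: pd.DataFrame) -> pd.DataFrame:
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"removed {(~keep).sum()} constant expression rows before network construction",
            stacklevel=3,
        )
    return values.loc[keep]


def adjacency(values: pd.DataFrame, beta: float, network_type: str = "unsigned") -> np.ndarray:
    """Soft-thresholded adjacency from gene-wise Pearson correlations.

    unsigned: ``|cor|^beta``; signed: ``((1 + cor) / 2)^beta``.  Diagonal 1.
    """
    if beta < 1:
        raise InvalidInputError(f"beta must be >= 1, got {beta}")
    cor = np.corrcoef(values.to_numpy())
    cor = np.clip(cor, -1.0, 1.0)
    if network_type == "unsigned":
        adj = np.abs(cor) ** beta
    elif network_type == "signed":
        adj = ((1.0 + cor) / 2.0) ** beta
    else:
        raise InvalidInputError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(adj, 1.0)
    return adj


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """(R², slope) of log10 p(k) regressed on log10 mean-k over degree bins."""
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    logp, logk = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        logp.append(np.log10(members.size / k.size))
        logk.append(np.log10(members.mean()))
    if len(logk) < 3:
        return 0.0, 0.0
    res = stats.linregress(logk, logp)
    return float(res.rvalue**2), float(res.slope)


def pick_soft_threshold(
    expr: ExpressionMatrix | pd.DataFrame, config: CoexpressionConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power by scale-free model fit.

    For each candidate β the network connectivity ``k_i = Σ_{j≠i} a_ij`` is
    binned, and log10 p(k) is regressed on log10 k; the smallest β whose fit
    reaches the R² threshold with a negative slope (a decreasing degree
    distribution, as scale-free topology requires) is returned.  If no
    candidate qualifies, the β maximizing R² (among negative-slope fits,
    else overall) is returned with a warning.
    """
    config = config or CoexpressionConfig()
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    values = _drop_constant_rows(values)
    if values.shape[1] < 3:
        raise InvalidInputError("need >= 3 samples for network construction")
    if values.shape[0] < config.min_module_size:
        raise InvalidInputError(
            f"need >= {config.min_module_size} genes, got {values.shape[0]}"
        )

    cor = np.clip(np.corrcoef(values.to_numpy()), -1.0, 1.0)
    base = np.abs(cor) if config.network_type == "unsigned" else (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)  # connectivity excludes self

    rows = []
    for beta in config.candidate_betas:
        k = (base**beta).sum(axis=1)
        r2, slope = _scale_free_fit(k, config.n_degree_bins)
        rows.append({"beta": beta, "r_squared": r2, "slope": slope, "mean_k": float(k.mean())})
    fit_table = pd.DataFrame(rows)

    # powers that leave the network essentially disconnected are excluded:
    # the scale-free fit becomes vacuously good as all connectivities -> 0
    connected = fit_table[fit_table.mean_k >= config.min_mean_connectivity]
    if connected.empty:
        connected = fit_table.iloc[:1]
    ok = connected[
        (connected.r_squared > config.scale_free_r2_threshold) & (connected.slope < 0)
    ]
    if not ok.empty:
        beta = int(ok.iloc[0]["beta"])
    else:
        neg = connected[connected.slope < 0]
        pool = neg if not neg.empty else connected
        beta = int(pool.loc[pool.r_squared.idxmax(), "beta"])
        warnings.warn(
            f"no candidate beta reached scale-free R^2 > {config.scale_free_r2_threshold} "
            f"at mean connectivity >= {config.min_mean_connectivity}; "
            f"falling back to beta={beta} (max R^2 = {pool.r_squared.max():.3f})",
            stacklevel=2,
        )
    return beta, fit_table


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a soft-thresholded adjacency.

    ``t_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)``
    with ``k_i = Σ_{j≠i} a_ij``; diagonal 1.  Entries lie in [0, 1] for
    adjacencies in [0, 1].
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise InvalidInputError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise InvalidInputError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # (i,j) entry = Σ_u a_iu a_uj over u≠i,j since diag(a)=0
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(values: np.ndarray) -> np.ndarray:
    """Unit-norm first right singular vector of standardized module expression.

    Sign oriented to correlate positively with the module's mean expression
    profile across samples, so merging decisions are deterministic.
    """
    z = values - values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]
    # right singular vector over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    norm = np.linalg.norm(eig)
    return eig / norm if norm > 0 else eig


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    uc, vc = u - u.mean(), v - v.mean()
    denom = np.linalg.norm(uc) * np.linalg.norm(vc)
    return float(uc @ vc / denom) if denom > 0 else 0.0


def detect_modules(
    expr: ExpressionMatrix | pd.DataFrame, config: CoexpressionConfig | None = None
) -> ModuleAssignment:
    """Detect coexpression modules on a (typically significant-gene) matrix.

    Steps: soft-threshold selection → adjacency → TOM → average-linkage
    clustering on 1 − TOM → static cut at the configured quantile of merge
    heights → minimum-size and cohesion filtering → iterative eigengene
    merging at the configured dissimilarity threshold → labels ordered by
    descending module size.
    """
    config = config or CoexpressionConfig()
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    values = _drop_constant_rows(values)
    genes = values.index
    n_genes = values.shape[0]

    if n_genes < config.min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned", stacklevel=2)
        labels = pd.Series(UNASSIGNED, index=genes, name="module")
        empty_fit = pd.DataFrame(columns=["beta", "r_squared", "slope", "mean_k"])
        return ModuleAssignment(labels, pd.DataFrame(index=range(values.shape[1])), 0, empty_fit)

    beta, fit_table = pick_soft_threshold(values, config)
    adj = adjacency(values, beta, config.network_type)
    tom = tom_similarity(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0  # symmetrize away rounding noise

    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    heights = link[:, 2]
    cut = float(np.quantile(heights, config.cut_quantile))
    arr = values.to_numpy()

    # subtrees entirely below the cut are the initial clusters
    tree = hierarchy.to_tree(link)
    initial: list = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf() or node.dist <= cut:
            initial.append(node)
        else:
            stack.extend([node.get_left(), node.get_right()])

    def refine(node) -> list:
        """Split a cluster while its two subtree children are both
        module-sized and their eigengenes are at least merge_threshold
        apart — the exact dissimilarity the merge step uses, so refinement
        never undoes what merging would rejoin."""
        if node.is_leaf() or node.count < 2 * config.min_module_size:
            return [node]
        left, right = node.get_left(), node.get_right()
        if left.count < config.min_module_size or right.count < config.min_module_size:
            return [node]
        eig_l = _eigengene(arr[left.pre_order()])
        eig_r = _eigengene(arr[right.pre_order()])
        if 1.0 - _pearson(eig_l, eig_r) >= config.merge_threshold:
            return refine(left) + refine(right)
        return [node]

    clusters: list[np.ndarray] = []
    for node in initial:
        for part in refine(node):
            members = np.array(sorted(part.pre_order()))
            if members.size < config.min_module_size:
                continue
            eig = _eigengene(arr[members])
            cohesion = np.median([abs(_pearson(arr[m], eig)) for m in members])
            if cohesion >= config.min_module_cohesion:
                clusters.append(members)

    # iterative eigengene merging: closest pair first
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        eigs = [_eigengene(arr[c]) for c in clusters]
        best_pair, best_diss = None, config.merge_threshold
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = 1.0 - _pearson(eigs[i], eigs[j])
                if d < best_diss:
                    best_pair, best_diss = (i, j), d
        if best_pair is not None:
            i, j = best_pair
            clusters[i] = np.sort(np.concatenate([clusters[i], clusters[j]]))
            del clusters[j]
            merged = True

    clusters.sort(key=lambda c: (-c.size, c[0]))
    labels = pd.Series(UNASSIGNED, index=genes, name="module")
    eig_cols = {}
    for rank, members in enumerate(clusters, start=1):
        name = f"M{rank}"
        labels.iloc[members] = name
        eig_cols[name] = _eigengene(arr[members])
    eigengenes = pd.DataFrame(eig_cols, index=values.columns)
    return ModuleAssignment(labels, eigengenes, beta, fit_table)


def tf_subnetwork(
    expr: ExpressionMatrix | pd.DataFrame,
    assignment: ModuleAssignment,
    tf_list: Iterable[str],
    min_abs_weight: float = 0.0,
) -> pd.DataFrame:
    """Within-module correlation edges with >= 1 transcription-factor endpoint.

    Returns a DataFrame with columns ``source, target, module, weight,
    abs_weight, p_value, tf_source, tf_target``, sorted by descending
    ``|weight|``.  ``p_value`` is the two-sided correlation-test p for the
    edge, emitted for reference; the primary edge strength is the
    correlation itself.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    tfs = normalize_symbols(tf_list)
    if not tfs:
        raise InvalidInputError("transcription-factor list is empty")

    n_samples = values.shape[1]
    rows = []
    any_tf = False
    for module in assignment.module_sizes.index:
        members = [g for g in assignment.genes_in(module) if g in values.index]
        member_tf = [g for g in members if normalize_symbol(str(g)) in tfs]
        if not member_tf:
            continue
        any_tf = True
        sub = values.loc[members].to_numpy()
        cor = np.clip(np.corrcoef(sub), -1.0, 1.0)
        for i, gi in enumerate(members):
            for j in range(i + 1, len(members)):
                gj = members[j]
                ti = normalize_symbol(str(gi)) in tfs
                tj = normalize_symbol(str(gj)) in tfs
                if not (ti or tj):
                    continue
                w = float(cor[i, j])
                if abs(w) < min_abs_weight:
                    continue
                # t-test p for a Pearson correlation with n-2 df
                r = min(abs(w), 1 - 1e-12)
                t = r * np.sqrt((n_samples - 2) / (1 - r**2))
                p = float(2 * stats.t.sf(t, n_samples - 2))
                rows.append(
                    {
                        "source": gi,
                        "target": gj,
                        "module": module,
                        "weight": w,
                        "abs_weight": abs(w),
                        "p_value": p,
                        "tf_source": ti,
                        "tf_target": tj,
                    }
                )
    if not any_tf:
        warnings.warn("no transcription factor found in any module; empty edge list", stacklevel=2)
    edges = pd.DataFrame(
        rows,
        columns=["source", "target", "module", "weight", "abs_weight", "p_value", "tf_source", "tf_target"],
    )
    if not edges.empty:
        edges = edges.sort_values("abs_weight", ascending=False, kind="stable").reset_index(drop=True)
    return edges
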