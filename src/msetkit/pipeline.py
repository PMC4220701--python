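"""End-to-end orchestration: simulate → DE → enrichment → modules → qPCR.

One :class:`PipelineConfig` (YAML or JSON on disk) drives the full workflow:

1. obtain inputs — either synthetic data with planted truth, or
   user-supplied files (expression TSV + sample sheet, GMT databases, a
   transcription-factor list, a Cq table);
2. two-group differential expression; significant sets at a primary cutoff
   (0.01) and a wider data-mining cutoff (0.03);
3. MSET randomization enrichment of the primary significant set against
   every database, plus two pooled databases (union of all sources, and
   genes in >= 2 sources) and a pairwise overlap report;
4. coexpression module detection on the significant-gene submatrix and
   transcription-factor subnetwork export;
5. qPCR confirmation with the efficiency-corrected ratio and randomization
   test.

All stage seeds derive from a single master seed, so re-running an
identical config reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._seeds import child_seed
from .coexpression import (
    UNASSIGNED,
    CoexpressionConfig,
    detect_modules,
    tf_subnetwork,
)
from .diffexpr import (
    ExpressionMatrix,
    fit_two_group,
    read_expression_tsv,
    significant_set,
    write_expression_tsv,
)
from .errors import MsetkitError
from .genesets import (
    DatabaseCollection,
    overlap_table,
    pool_min_membership,
    pool_union,
    read_gmt,
    write_gmt,
)
from .mset import MsetConfig, match_report, mset_batch
from .qpcr import CqTable, analyze_qpcr
from .synthetic import (
    GROUP_A,
    GROUP_B,
    DeSpec,
    GenesetSpec,
    ModuleSpec,
    QpcrSpec,
    UniverseSpec,
    simulate_expression,
    simulate_genesets,
    simulate_qpcr,
    simulate_universe,
)

logger = logging.getLogger("msetkit.pipeline")

__all__ = ["PipelineConfig", "InputPaths", "RunReport", "run_pipeline", "validate_config"]


@dataclass
class InputPaths:
    """User-supplied files; all must exist when synthetic mode is off."""

    expression: str = ""
    samples: str = ""
    gmt: str = ""
    tf_list: str = ""
    cq_table: str = ""


@dataclass
class SyntheticScenario:
    """Shapes of the synthetic study when no input files are given.

    Defaults mirror the study design this pipeline emulates: a ~20,000-gene
    background with ~5% transcription factors, 6 arrays per group, ~1,000
    planted differentially expressed genes with a ±0.75 log2 shift, five
    enriched disease databases of 300–700 genes (enrichment fraction 0.3,
    shared core 50), three unenriched negative-control databases, and a
    10-per-group qPCR confirmation of six targets against two reference
    genes.
    """

    n_genes: int = 20_000
    n_tf: int = 1_000
    n_per_group: int = 6
    n_de: int = 1_000
    effect_log2: float = 0.75
    noise_sd_log2: float = 0.25
    enriched_sizes: tuple[int, ...] = (359, 450, 550, 650, 700)
    enriched_names: tuple[str, ...] = (
        "addiction_db1",
        "addiction_db2",
        "addiction_db3",
        "addiction_db4",
        "addiction_db5",
    )
    control_sizes: tuple[int, ...] = (400, 500, 600)
    control_names: tuple[str, ...] = ("control_db1", "control_db2", "control_db3")
    enrichment_fraction: float = 0.3
    shared_core_size: int = 50
    qpcr_n_targets: int = 6
    qpcr_n_per_group: int = 10
    qpcr_noise_sd: float = 0.15


@dataclass
class PipelineConfig:
    master_seed: int = 0
    alpha_primary: float = 0.01
    alpha_mining: float = 0.03
    n_randomizations: int = 10_000
    qpcr_iterations: int = 2000
    reference_genes: tuple[str, ...] = ("Ywhaz", "Ppia")
    coexpression: CoexpressionConfig = field(default_factory=CoexpressionConfig)
    inputs: InputPaths | None = None
    synthetic: SyntheticScenario = field(default_factory=SyntheticScenario)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "coexpression" in raw and isinstance(raw["coexpression"], dict):
            co = dict(raw["coexpression"])
            if "candidate_betas" in co:
                co["candidate_betas"] = tuple(co["candidate_betas"])
            raw["coexpression"] = CoexpressionConfig(**co)
        if "inputs" in raw and isinstance(raw["inputs"], dict):
            raw["inputs"] = InputPaths(**raw["inputs"])
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            syn = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["synthetic"].items()
            }
            raw["synthetic"] = SyntheticScenario(**syn)
        if "reference_genes" in raw:
            raw["reference_genes"] = tuple(raw["reference_genes"])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class RunReport:
    """Per-stage summaries plus provenance; serialized as report.json."""

    config_digest: str
    master_seed: int
    stage_summaries: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    artifact_digests: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def validate_config(config: PipelineConfig) -> list[str]:
    """All invariant violations as human-readable findings; empty iff runnable."""
    findings = []
    if not (0 < config.alpha_primary <= 1):
        findings.append(f"alpha_primary must be in (0, 1], got {config.alpha_primary}")
    if not (0 < config.alpha_mining <= 1):
        findings.append(f"alpha_mining must be in (0, 1], got {config.alpha_mining}")
    if config.alpha_primary > config.alpha_mining:
        findings.append(
            f"alpha_primary ({config.alpha_primary}) must be <= alpha_mining "
            f"({config.alpha_mining})"
        )
    if config.n_randomizations < 100:
        findings.append(f"n_randomizations must be >= 100, got {config.n_randomizations}")
    if config.qpcr_iterations < 1000:
        findings.append(f"qpcr_iterations must be >= 1000, got {config.qpcr_iterations}")
    if len(config.reference_genes) < 1:
        findings.append("at least one reference gene required")
    if config.inputs is not None:
        for fname in dataclasses.fields(config.inputs):
            path = getattr(config.inputs, fname.name)
            if path and not Path(path).exists():
                findings.append(f"input path does not exist: {path} ({fname.name})")
    else:
        syn = config.synthetic
        if syn.n_de > syn.n_genes:
            findings.append(f"n_de ({syn.n_de}) exceeds n_genes ({syn.n_genes})")
        if syn.n_tf > syn.n_genes:
            findings.append(f"n_tf ({syn.n_tf}) exceeds n_genes ({syn.n_genes})")
    return findings


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute the full workflow; artifacts land in ``out_dir``.

    Raises :class:`MsetkitError` naming the failing stage; artifacts of the
    stages already completed are retained.
    """
    findings = validate_config(config)
    if findings:
        raise MsetkitError("invalid config: " + "; ".join(findings))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_digest=config.digest(), master_seed=config.master_seed)
    seed = config.master_seed
    stage = "inputs"
    try:
        # ------------------------------------------------------------ inputs
        if config.inputs is None:
            syn = config.synthetic
            universe = simulate_universe(
                UniverseSpec(n_genes=syn.n_genes, n_tf=syn.n_tf, seed=child_seed(seed, "universe"))
            )
            expr, truth = simulate_expression(
                universe,
                DeSpec(
                    n_per_group=syn.n_per_group,
                    n_de=syn.n_de,
                    effect_log2=syn.effect_log2,
                    noise_sd_log2=syn.noise_sd_log2,
                    seed=child_seed(seed, "expression"),
                ),
            )
            enriched = simulate_genesets(
                universe,
                truth,
                GenesetSpec(
                    sizes=syn.enriched_sizes,
                    names=syn.enriched_names,
                    enrichment_fraction=syn.enrichment_fraction,
                    shared_core_size=syn.shared_core_size,
                    seed=child_seed(seed, "genesets_enriched"),
                ),
            )
            controls = simulate_genesets(
                universe,
                truth,
                GenesetSpec(
                    sizes=syn.control_sizes,
                    names=syn.control_names,
                    enrichment_fraction=0.0,
                    shared_core_size=0,
                    seed=child_seed(seed, "genesets_control"),
                ),
            )
            collection = DatabaseCollection([*enriched, *controls])
            tf_genes = sorted(universe.tf_symbols)
            background = list(universe.symbols)

            universe.write(out / "background.txt", out / "tf_list.txt")
            write_expression_tsv(expr, out / "expression.tsv", out / "samples.tsv")
            truth.to_csv(out / "truth_de.tsv", sep="\t", index=False)
            write_gmt(collection, out / "databases.gmt")
            cq_spec = None  # built after DE so targets carry planted ratios
        else:
            paths = config.inputs
            expr = read_expression_tsv(paths.expression, paths.samples)
            collection = read_gmt(paths.gmt)
            tf_genes = [
                line.strip()
                for line in Path(paths.tf_list).read_text().splitlines()
                if line.strip()
            ] if paths.tf_list else []
            background = [str(g) for g in expr.gene_ids]
            truth = None
            cq_spec = None

        # ------------------------------------------------- differential expression
        stage = "diffexpr"
        groups = expr.group_names
        group_a = GROUP_A if GROUP_A in groups else groups[0]
        group_b = GROUP_B if GROUP_B in groups else [g for g in groups if g != group_a][0]
        de = fit_two_group(expr, group_a=group_a, group_b=group_b)
        de.to_tsv(out / "diffexpr.tsv")
        sig_primary = significant_set(de, config.alpha_primary)
        sig_mining = significant_set(de, config.alpha_mining)
        (out / "significant_primary.txt").write_text("\n".join(sorted(sig_primary.genes)) + "\n")
        (out / "significant_mining.txt").write_text("\n".join(sorted(sig_mining.genes)) + "\n")
        report.stage_summaries["diffexpr"] = {
            "n_genes": int(de.table.shape[0]),
            "n_significant_primary": len(sig_primary),
            "n_significant_mining": len(sig_mining),
            "alpha_primary": config.alpha_primary,
            "alpha_mining": config.alpha_mining,
        }
        logger.info(
            "diffexpr: %d genes, %d significant at %.3g, %d at %.3g",
            de.table.shape[0], len(sig_primary), config.alpha_primary,
            len(sig_mining), config.alpha_mining,
        )

        # ------------------------------------------------------------ gene sets
        stage = "genesets"
        pooled_union = pool_union(collection, name="pooled_union")
        pooled_min2 = pool_min_membership(collection, k=2, name="pooled_min2")
        full_collection = DatabaseCollection([*collection, pooled_union, pooled_min2])
        write_gmt(DatabaseCollection([pooled_union, pooled_min2]), out / "pooled.gmt")
        overlaps = overlap_table(collection)
        overlaps.to_csv(out / "overlap.tsv", sep="\t", index=False)
        report.stage_summaries["genesets"] = {
            "n_databases": len(collection),
            "pooled_union_size": len(pooled_union),
            "pooled_min2_size": len(pooled_min2),
        }

        # ---------------------------------------------------------------- MSET
        stage = "mset"
        mset_cfg = MsetConfig(
            n_randomizations=config.n_randomizations, seed=child_seed(seed, "mset")
        )
        mset_tables = {}
        for label, sig in (("primary", sig_primary), ("mining", sig_mining)):
            table, _ = mset_batch(sig, full_collection, background, mset_cfg)
            table.to_csv(out / f"mset_{label}.tsv", sep="\t", index=False)
            mset_tables[label] = table
        reportable = match_report(sig_mining, collection)
        reportable.to_csv(out / "match_report.tsv", sep="\t")
        report.stage_summaries["mset"] = {
            "alpha": {
                "primary": config.alpha_primary,
                "mining": config.alpha_mining,
            },
            "n_randomizations": config.n_randomizations,
            "primary": {
                row["database"]: {
                    "x": int(row["x"]),
                    "K": int(row["K"]),
                    "empirical_p": float(row["empirical_p"]),
                    "oracle_p": float(row["oracle_p"]),
                }
                for _, row in mset_tables["primary"].iterrows()
                if not row["error"]
            },
            "n_matched_genes": int(reportable.shape[0]),
        }

        # -------------------------------------------------------- coexpression
        stage = "coexpression"
        sig_genes_in_matrix = [g for g in expr.gene_ids if str(g).upper() in sig_primary.genes]
        sub = expr.values.loc[sig_genes_in_matrix]
        if sub.shape[0] >= config.coexpression.min_module_size:
            assignment = detect_modules(sub, config.coexpression)
            assignment.labels.to_frame().to_csv(out / "modules.tsv", sep="\t", index_label="gene")
            assignment.scale_free_fit_table.to_csv(out / "scale_free_fit.tsv", sep="\t", index=False)
            edges = tf_subnetwork(sub, assignment, tf_genes) if tf_genes else pd.DataFrame()
            edges.to_csv(out / "tf_edges.tsv", sep="\t", index=False)
            report.stage_summaries["coexpression"] = {
                "chosen_beta": int(assignment.chosen_beta),
                "module_sizes": {
                    str(k): int(v) for k, v in assignment.module_sizes.items()
                },
                "n_unassigned": int((assignment.labels == UNASSIGNED).sum()),
                "n_tf_edges": int(edges.shape[0]),
            }
        else:
            report.warnings.append(
                f"coexpression skipped: only {sub.shape[0]} significant genes "
                f"(< min_module_size {config.coexpression.min_module_size})"
            )

        # ---------------------------------------------------------------- qPCR
        stage = "qpcr"
        if config.inputs is None and truth is not None:
            syn = config.synthetic
            # confirm the strongest planted changes, half up half down
            n_targets = min(syn.qpcr_n_targets, len(truth))
            up = truth[truth.direction > 0]["gene"].tolist()
            down = truth[truth.direction < 0]["gene"].tolist()
            targets = (up[: (n_targets + 1) // 2] + down[: n_targets // 2])[:n_targets]
            ratios = {
                g: float(truth.set_index("gene").loc[g, "true_ratio"]) for g in targets
            }
            for ref in config.reference_genes:
                ratios[ref] = 1.0
            cq = simulate_qpcr(
                QpcrSpec(
                    target_ratios=ratios,
                    reference_genes=config.reference_genes,
                    n_per_group=syn.qpcr_n_per_group,
                    cq_noise_sd=syn.qpcr_noise_sd,
                    seed=child_seed(seed, "qpcr_sim"),
                )
            )
            cq.to_tsv(out / "cq_table.tsv")
        elif config.inputs is not None and config.inputs.cq_table:
            cq = CqTable.from_tsv(config.inputs.cq_table)
            targets = [g for g in cq.genes if g not in config.reference_genes]
        else:
            cq = None
            targets = []
        if cq is not None and targets:
            qpcr_table = analyze_qpcr(
                cq,
                targets,
                list(config.reference_genes),
                group_a,
                group_b,
                iterations=config.qpcr_iterations,
                seed=child_seed(seed, "qpcr_test"),
            )
            qpcr_table.to_csv(out / "qpcr_results.tsv", sep="\t", index=False)
            report.stage_summaries["qpcr"] = {
                row["gene"]: {"ratio": float(row["ratio"]), "p_value": float(row["p_value"])}
                for _, row in qpcr_table.iterrows()
            }

    except MsetkitError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise MsetkitError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "report"
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "report.json":
            report.artifact_digests[path.name] = _sha256(path)
    report.to_json(out / "report.json")
    return report
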