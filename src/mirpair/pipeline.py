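"""End-to-end orchestration: simulate/load, DE, clustering, integration,
qPCR validation and report generation.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives the
run.  Every stage writes its outputs as TSV/JSON under the output
directory, and a manifest records the seed, configuration, stage list and
SHA-256 hashes of every written file, so a rerun with the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import clustering, diffexpr, integration, qpcr
from .io import (
    ExpressionMatrix,
    read_annotation,
    read_ct_table,
    read_expression_tsv,
    read_gene_sets,
    read_predictions,
    read_sample_sheet,
    write_annotation,
    write_ct_table,
    write_expression_tsv,
    write_gene_sets,
    write_predictions,
    write_sample_sheet,
)
from .synthetic import SimulationConfig, evaluate_recovery, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "StudyReport"]

DEFAULT_COMPARISONS = (
    ("active_UC", "control"),
    ("inactive_UC", "control"),
    ("active_UC", "inactive_UC"),
)


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on."""

    outdir: str = "mirpair_out"
    seed: int = 0
    # either simulate (default) or load the listed input TSVs
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mirna_expr_path: Optional[str] = None
    mrna_expr_path: Optional[str] = None
    sample_sheet_path: Optional[str] = None
    predictions_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    annotation_path: Optional[str] = None
    ct_path: Optional[str] = None
    quantile_normalize: bool = False
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    corr_alpha: float = 0.05
    correlation_groups: tuple[str, str] = ("active_UC", "control")
    cluster_k: int = 20
    top_k: int = 10
    qpcr_calibrator: str = "control"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.fdr_threshold <= 0 or self.corr_alpha <= 0:
            raise ValueError("thresholds must be positive")
        known = {"active_UC", "inactive_UC", "control", "CDc", "IC"}
        for a, b in self.comparisons:
            if a not in known or b not in known:
                raise ValueError(f"comparison references unknown group: {a} vs {b}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            for key in ("mirna_group_sizes", "mrna_group_sizes"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        if "correlation_groups" in raw:
            raw["correlation_groups"] = tuple(raw["correlation_groups"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["comparisons"] = [list(c) for c in self.comparisons]
        return out


class PairRow(BaseModel):
    mirna_id: str
    gene_symbol: str
    category: str
    rho: float
    p: float
    fdr: float


class ComparisonCounts(BaseModel):
    comparison: str
    platform: str
    total: int
    up: int
    down: int


class StudyReport(BaseModel):
    """Machine-readable summary of one pipeline run."""

    seed: int
    de_counts: list[ComparisonCounts]
    venn_mirna: dict[str, int]
    n_consensus_pairs: int
    n_candidate_pairs: int
    n_clinical_pairs: int
    n_significant_pairs: int
    category_tallies: dict[str, int]
    top_pairs: list[PairRow]
    recovery_sensitivity: Optional[float] = None
    recovery_precision: Optional[float] = None
    qpcr: list[dict] = []
    missing_sections: list[str] = []


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _de_for(
    matrix: ExpressionMatrix,
    sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    fit = diffexpr.fit_two_group(matrix, sheet, group_a, group_b)
    moderated = diffexpr.moderate_variances(fit.s_sq, fit.df_residual)
    return diffexpr.de_table(fit, moderated, config.fc_threshold, config.fdr_threshold)


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = ("all",)) -> dict:
    """Run the requested stages and return the manifest.

    Stage names: simulate, de, cluster, integrate, qpcr, report; "all"
    expands to every stage.  Later stages recompute their (cheap,
    deterministic) prerequisites, so each can be requested alone.
    """
    wanted = set(stages)
    if "all" in wanted:
        wanted = {"simulate", "de", "cluster", "integrate", "qpcr", "report"}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}, "config": config.to_dict()}
    timings: dict[str, float] = {}

    def _stage_done(name: str, t0: float) -> None:
        timings[name] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(name)
        logger.info("stage %-9s done in %.2fs", name, timings[name])

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    if config.simulate:
        sim_config = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
        study = simulate_study(sim_config)
        mirna_expr, mrna_expr = study["mirna_expr"], study["mrna_expr"]
        sheet, truth = study["sheet"], study["truth"]
        predictions, gene_sets, ct = study["predictions"], study["gene_sets"], study["ct"]
        if "simulate" in wanted:
            write_expression_tsv(mirna_expr, outdir / "mirna_expression.tsv")
            write_expression_tsv(mrna_expr, outdir / "mrna_expression.tsv")
            write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
            write_predictions(predictions, outdir / "predictions.tsv")
            write_gene_sets(gene_sets, outdir / "gene_sets.tsv")
            write_ct_table(ct, outdir / "ct_table.tsv")
            write_annotation(truth.annotation, outdir / "annotation.tsv")
            pd.DataFrame(
                [{"mirna_id": m, "gene_symbol": g} for m, g in truth.pairs]
            ).to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
            with open(outdir / "simulation_config.json", "w") as handle:
                json.dump(asdict(sim_config), handle, indent=2)
    else:
        required = {
            "mirna_expr_path": config.mirna_expr_path,
            "mrna_expr_path": config.mrna_expr_path,
            "sample_sheet_path": config.sample_sheet_path,
            "predictions_path": config.predictions_path,
            "gene_sets_path": config.gene_sets_path,
        }
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ValueError(f"[inputs] missing input paths: {missing}")
        mirna_expr = read_expression_tsv(config.mirna_expr_path)
        mrna_expr = read_expression_tsv(config.mrna_expr_path)
        sheet = read_sample_sheet(config.sample_sheet_path)
        predictions = read_predictions(config.predictions_path)
        gene_sets = read_gene_sets(config.gene_sets_path)
        ct = read_ct_table(config.ct_path) if config.ct_path else None
    if config.annotation_path:
        annotation = read_annotation(config.annotation_path)
    else:
        annotation = truth.annotation if truth is not None else None
    if config.quantile_normalize:
        mirna_expr = diffexpr.quantile_normalize(mirna_expr)
        mrna_expr = diffexpr.quantile_normalize(mrna_expr)
    _stage_done("simulate" if config.simulate else "load", t0)

    # --- differential expression -----------------------------------------
    de_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    t0 = time.perf_counter()
    for platform, matrix in (("miRNA", mirna_expr), ("mRNA", mrna_expr)):
        for group_a, group_b in config.comparisons:
            try:
                table = _de_for(matrix, sheet, group_a, group_b, config)
            except ValueError as exc:
                logger.warning("[de] skipping %s %s vs %s: %s", platform, group_a, group_b, exc)
                continue
            de_tables[(platform, group_a, group_b)] = table
            if "de" in wanted:
                table.to_csv(
                    outdir / f"de_{platform}_{group_a}_vs_{group_b}.tsv", sep="\t", index=False
                )
    if "de" in wanted:
        _stage_done("de", t0)

    # --- clustering -------------------------------------------------------
    if "cluster" in wanted:
        t0 = time.perf_counter()
        for platform, matrix in (("miRNA", mirna_expr), ("mRNA", mrna_expr)):
            top = clustering.top_variable_features(matrix, config.cluster_k)
            sub = ExpressionMatrix(
                tuple(top),
                matrix.sample_ids,
                matrix.to_frame().loc[top].to_numpy(),
            )
            row_d = clustering.agglomerate_complete(sub.values, axis="rows")
            col_d = clustering.agglomerate_complete(sub.values, axis="columns")
            ordered, row_order, col_order = clustering.heatmap_export(sub, row_d, col_d)
            write_expression_tsv(ordered, outdir / f"heatmap_{platform}.tsv")
            sidecar = {
                "rows": {"merges": row_d.merges, "heights": row_d.heights, "leaf_order": row_order},
                "columns": {"merges": col_d.merges, "heights": col_d.heights, "leaf_order": col_order},
            }
            with open(outdir / f"heatmap_{platform}.json", "w") as handle:
                json.dump(sidecar, handle, indent=2, default=list)
        _stage_done("cluster", t0)

    # --- integration ------------------------------------------------------
    t0 = time.perf_counter()
    key_mirna = ("miRNA", *config.correlation_groups)
    key_mrna = ("mRNA", *config.correlation_groups)
    ranked = None
    consensus = candidates = clinical = None
    if key_mirna in de_tables and key_mrna in de_tables:
        consensus = integration.consensus_targets(predictions)
        candidates = integration.candidate_pairs(
            consensus, de_tables[key_mirna], de_tables[key_mrna], annotation
        )
        clinical = integration.clinical_filter(candidates, gene_sets)
        correlated = integration.correlate_pairs(
            clinical, mirna_expr, mrna_expr, sheet, config.correlation_groups
        )
        ranked = integration.rank_pairs(correlated, config.corr_alpha)
        if "integrate" in wanted:
            ranked.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
            _stage_done("integrate", t0)
    else:
        logger.warning("[integrate] DE tables for %s unavailable; skipped", config.correlation_groups)

    # --- qPCR validation --------------------------------------------------
    qpcr_rows: list[dict] = []
    if "qpcr" in wanted and ct is not None and len(ct):
        t0 = time.perf_counter()
        rq = qpcr.relative_quantity_ddct(ct, config.qpcr_calibrator, sheet)
        group_a, group_b = config.correlation_groups
        de_mirna_table = de_tables.get(key_mirna)
        for feature in sorted(rq["feature"].unique()):
            test, fc = qpcr.qpcr_group_test(rq, group_a, group_b, sheet, feature=feature)
            row = {"feature": feature, "fold_change": fc, "U": test.statistic, "p": test.p_value}
            if de_mirna_table is not None and feature in set(de_mirna_table["feature_id"]):
                array_fc = float(
                    de_mirna_table.set_index("feature_id").loc[feature, "log2FC"]
                )
                if fc != 0 and array_fc != 0:
                    row["concordance"] = qpcr.concordance_check(fc, array_fc)
            qpcr_rows.append(row)
        rq.to_csv(outdir / "qpcr_rq.tsv", sep="\t", index=False)
        pd.DataFrame(qpcr_rows).to_csv(outdir / "qpcr_tests.tsv", sep="\t", index=False)
        _stage_done("qpcr", t0)

    # --- report -----------------------------------------------------------
    if "report" in wanted:
        t0 = time.perf_counter()
        report = write_report(
            outdir,
            config,
            de_tables,
            consensus,
            candidates,
            clinical,
            ranked,
            qpcr_rows,
            truth,
        )
        manifest["report"] = json.loads(report.model_dump_json())
        _stage_done("report", t0)

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    manifest["timings_s"] = timings
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def write_report(
    outdir: Path,
    config: PipelineConfig,
    de_tables: dict,
    consensus,
    candidates,
    clinical,
    ranked,
    qpcr_rows: list[dict],
    truth,
) -> StudyReport:
    """Assemble, validate and write the study report JSON."""
    missing: list[str] = []
    de_counts = []
    for (platform, a, b), table in sorted(de_tables.items()):
        sig = table[table["significant"]]
        de_counts.append(
            ComparisonCounts(
                comparison=f"{a}_vs_{b}",
                platform=platform,
                total=len(sig),
                up=int((sig["log2FC"] > 0).sum()),
                down=int((sig["log2FC"] < 0).sum()),
            )
        )
    venn = {"total": 0, "up": 0, "down": 0}
    key1 = ("miRNA", "active_UC", "control")
    key2 = ("miRNA", "active_UC", "inactive_UC")
    if key1 in de_tables and key2 in de_tables:
        venn = diffexpr.venn_overlap(de_tables[key1], de_tables[key2])
    else:
        missing.append("venn_mirna")

    if ranked is not None:
        sig = ranked[ranked["significant"]]
        tallies = sig["category"].value_counts().to_dict() if len(sig) else {}
        top = [
            PairRow(
                mirna_id=r.mirna_id,
                gene_symbol=r.gene_symbol,
                category=r.category,
                rho=float(r.rho),
                p=float(r.p),
                fdr=float(r.fdr),
            )
            for r in ranked.head(config.top_k).itertuples()
        ]
        n_sig = len(sig)
    else:
        missing.append("integration")
        tallies, top, n_sig = {}, [], 0

    sensitivity = precision = None
    if truth is not None and ranked is not None and truth.pairs:
        sensitivity, precision = evaluate_recovery(ranked[ranked["significant"]], truth)

    report = StudyReport(
        seed=config.seed,
        de_counts=de_counts,
        venn_mirna=venn,
        n_consensus_pairs=0 if consensus is None else len(consensus),
        n_candidate_pairs=0 if candidates is None else len(candidates),
        n_clinical_pairs=0 if clinical is None else len(clinical),
        n_significant_pairs=n_sig,
        category_tallies={str(k): int(v) for k, v in tallies.items()},
        top_pairs=top,
        recovery_sensitivity=sensitivity,
        recovery_precision=precision,
        qpcr=qpcr_rows,
        missing_sections=missing,
    )
    with open(outdir / "report.json", "w") as handle:
        handle.write(report.model_dump_json(indent=2))
    with open(outdir / "report.schema.json", "w") as handle:
        json.dump(StudyReport.model_json_schema(), handle, indent=2)
    if ranked is not None:
        ranked.head(config.top_k).to_csv(outdir / "top_pairs.tsv", sep="\t", index=False)
    return report
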