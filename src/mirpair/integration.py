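"""miRNA-target integration: consensus prediction, inverse-correlation
screening and clinical gene-set prioritization.

The procedure chains four filters:

1. **Consensus prediction** — keep a (miRNA, gene) pair only when enough
   independent prediction databases agree: at least 3 of the 5 standard
   databases (miRanda, miRDB, miRWalk, RNA22, TargetScan), or — for
   alternative mature miRNAs covered only by miRanda/miRWalk — at least 2
   of {miRanda, miRWalk, DianaMicroT}.
2. **Differential-expression gate** — both partners must be significantly
   differentially expressed in the case-control comparison, with opposite
   fold-change directions (consistent with repression).
3. **Spearman screening** — rank correlation of the two expression
   profiles across subjects profiled on both platforms, with
   Benjamini-Hochberg FDR over the pairs actually tested; a pair is
   significant when p < alpha and rho < 0.
4. **Clinical prioritization** — restriction to genes in curated clinical
   gene sets (UC susceptibility, barrier, cell-adhesion, anti-microbial).

Pairs flow through as a pandas DataFrame with one row per (miRNA, gene).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .io import (
    ALTERNATIVE_DATABASES,
    CATEGORY_LABELS,
    CATEGORY_PRIORITY,
    DATABASES,
    STANDARD_DATABASES,
    ExpressionMatrix,
)
from .stats_core import bh_adjust, spearman_p_tapprox, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "consensus_targets",
    "candidate_pairs",
    "correlate_pairs",
    "rank_pairs",
    "clinical_filter",
]

PAIR_KEY = ["mirna_id", "gene_symbol"]


def consensus_targets(
    records: pd.DataFrame,
    alternative_mirnas: Iterable[str] = (),
) -> pd.DataFrame:
    """Reduce per-database predictions to consensus (miRNA, gene) pairs.

    Standard miRNAs need >= 3 votes from the 5 standard databases
    (DianaMicroT votes are ignored for them); miRNAs listed in
    ``alternative_mirnas`` need >= 2 votes from miRanda/miRWalk/DianaMicroT.
    Returns columns mirna_id, gene_symbol, n_databases, databases, rule.
    """
    unknown = set(records["database"]) - set(DATABASES)
    if unknown:
        raise ValueError(f"unknown prediction databases: {sorted(unknown)}")
    alternative = set(alternative_mirnas)
    records = records.drop_duplicates(subset=["mirna_id", "gene_symbol", "database"])
    is_alt = records["mirna_id"].isin(alternative)
    allowed = np.where(
        is_alt,
        records["database"].isin(ALTERNATIVE_DATABASES),
        records["database"].isin(STANDARD_DATABASES),
    )
    votes = (
        records[allowed]
        .groupby(PAIR_KEY)["database"]
        .agg(n_databases="size", databases=lambda d: ";".join(sorted(d)))
        .reset_index()
    )
    votes["rule"] = np.where(
        votes["mirna_id"].isin(alternative), "alternative_2of3", "standard_3of5"
    )
    needed = np.where(votes["rule"] == "alternative_2of3", 2, 3)
    out = votes[votes["n_databases"] >= needed].reset_index(drop=True)
    return out.sort_values(PAIR_KEY, kind="stable").reset_index(drop=True)


def _best_probe_per_gene(
    de_mrna: pd.DataFrame, annotation: Optional[Mapping[str, str]]
) -> pd.DataFrame:
    """Collapse an mRNA DE table to one probe set per gene (smallest p).

    ``annotation`` maps probe-set IDs to gene symbols; when absent the
    feature IDs are taken to be gene symbols already.  Ties on p are
    broken lexicographically by feature ID.
    """
    table = de_mrna.copy()
    if annotation is None:
        table["gene_symbol"] = table["feature_id"]
    else:
        table["gene_symbol"] = table["feature_id"].map(lambda f: annotation.get(f))
        dropped = int(table["gene_symbol"].isna().sum())
        if dropped:
            logger.info("dropping %d mRNA probe sets without gene annotation", dropped)
        table = table.dropna(subset=["gene_symbol"])
    table = table.sort_values(["gene_symbol", "p", "feature_id"], kind="stable")
    return table.groupby("gene_symbol", as_index=False).first()


def candidate_pairs(
    consensus: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    annotation: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Apply the differential-expression and direction-opposition gates.

    Keeps consensus pairs whose miRNA is significant and whose gene has at
    least one significant probe set (the probe with the smallest DE p is
    used for the gene), with opposite fold-change signs.  Adds columns
    probe_id, mirna_log2FC, mrna_log2FC.
    """
    mirna_cols = de_mirna.set_index("feature_id")
    genes = _best_probe_per_gene(de_mrna, annotation).set_index("gene_symbol")
    merged = consensus.copy()
    known_mirna = merged["mirna_id"].isin(mirna_cols.index)
    known_gene = merged["gene_symbol"].isin(genes.index)
    skipped = int((~(known_mirna & known_gene)).sum())
    if skipped:
        logger.info("skipping %d consensus pairs absent from the DE tables", skipped)
    merged = merged[known_mirna & known_gene]
    merged = merged.assign(
        mirna_log2FC=mirna_cols.loc[merged["mirna_id"], "log2FC"].to_numpy(),
        mirna_significant=mirna_cols.loc[merged["mirna_id"], "significant"].to_numpy(),
        probe_id=genes.loc[merged["gene_symbol"], "feature_id"].to_numpy(),
        mrna_log2FC=genes.loc[merged["gene_symbol"], "log2FC"].to_numpy(),
        mrna_significant=genes.loc[merged["gene_symbol"], "significant"].to_numpy(),
    )
    keep = (
        merged["mirna_significant"]
        & merged["mrna_significant"]
        & (np.sign(merged["mirna_log2FC"]) != np.sign(merged["mrna_log2FC"]))
        & (merged["mirna_log2FC"] != 0)
        & (merged["mrna_log2FC"] != 0)
    )
    out = merged[keep].drop(columns=["mirna_significant", "mrna_significant"])
    return out.reset_index(drop=True)


def matched_subject_samples(
    sheet: pd.DataFrame, groups: Iterable[str]
) -> tuple[list[str], list[str]]:
    """Per-subject sample pairs (miRNA sample, mRNA sample) in the groups.

    Subjects profiled on both platforms, ordered by subject ID.  When a
    subject has several samples on a platform the lexicographically first
    is used.
    """
    groups = set(groups)
    sub = sheet[sheet["group"].isin(groups)]
    by_platform = {
        platform: frame.sort_values("sample_id").groupby("subject_id")["sample_id"].first()
        for platform, frame in sub.groupby("platform")
    }
    mirna = by_platform.get("miRNA", pd.Series(dtype=str))
    mrna = by_platform.get("mRNA", pd.Series(dtype=str))
    shared = sorted(set(mirna.index) & set(mrna.index))
    return [mirna[s] for s in shared], [mrna[s] for s in shared]


def correlate_pairs(
    pairs: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    groups: Iterable[str] = ("active_UC", "control"),
) -> pd.DataFrame:
    """Spearman rho and two-sided p for each pair over matched subjects.

    Correlation uses only subjects profiled on both platforms within the
    selected groups.  Pairs whose features are missing from the matrices,
    or with fewer than 3 matched subjects, are excluded (counted in the
    log).  Adds columns rho, p, n_samples.
    """
    mirna_samples, mrna_samples = matched_subject_samples(sheet, groups)
    n = len(mirna_samples)
    if n < 3:
        logger.warning("only %d matched subjects; no correlations computed", n)
        return pairs.iloc[0:0].assign(rho=[], p=[], n_samples=[])
    mirna_sub = mirna_expr.subset_samples(mirna_samples)
    mrna_sub = mrna_expr.subset_samples(mrna_samples)
    mirna_idx = {f: i for i, f in enumerate(mirna_sub.feature_ids)}
    mrna_idx = {f: i for i, f in enumerate(mrna_sub.feature_ids)}
    rhos, ps, keep = [], [], []
    missing = 0
    for row in pairs.itertuples():
        i = mirna_idx.get(row.mirna_id)
        j = mrna_idx.get(row.probe_id)
        if i is None or j is None:
            missing += 1
            keep.append(False)
            continue
        rho = spearman_rho(mirna_sub.values[i], mrna_sub.values[j])
        rhos.append(rho)
        ps.append(spearman_p_tapprox(rho, n))
        keep.append(True)
    if missing:
        logger.info("excluded %d pairs missing from the expression matrices", missing)
    out = pairs[keep].copy()
    out["rho"] = rhos
    out["p"] = ps
    out["n_samples"] = n
    return out.reset_index(drop=True)


def rank_pairs(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """FDR-adjust and rank correlated pairs.

    The Benjamini-Hochberg family is exactly the set of pairs entering
    this call.  Pairs are sorted by ascending p; a pair is significant
    when p < alpha and rho < 0 (inverse correlation, consistent with
    miRNA-mediated repression).
    """
    out = pairs.copy()
    if len(out) == 0:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["p"] < alpha) & (out["rho"] < 0)
    return out.sort_values(["p", "mirna_id", "gene_symbol"], kind="stable").reset_index(drop=True)


def clinical_filter(pairs: pd.DataFrame, catalog: Mapping[str, frozenset[str]]) -> pd.DataFrame:
    """Keep pairs whose gene belongs to at least one clinical category.

    Adds ``categories`` (all matches, in fixed priority order, ';'-joined)
    and ``category`` (display label of the highest-priority match).
    """
    if not catalog:
        raise ValueError("gene-set catalog is empty")
    def _cats(gene: str) -> list[str]:
        return [c for c in CATEGORY_PRIORITY if gene in catalog.get(c, frozenset())]

    matches = [_cats(g) for g in pairs["gene_symbol"]]
    keep = [bool(m) for m in matches]
    out = pairs[keep].copy()
    kept_matches = [m for m in matches if m]
    out["categories"] = [";".join(m) for m in kept_matches]
    out["category"] = [CATEGORY_LABELS[m[0]] for m in kept_matches]
    return out.reset_index(drop=True)
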