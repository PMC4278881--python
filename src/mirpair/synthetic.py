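"""Seeded generator of a complete synthetic paired-platform study.

Emulates the design of a paired miRNA/mRNA microarray case-control study
of ulcerative colitis: 10 active UC / 7 inactive UC / 10 control subjects
profiled on a miRNA platform, a subset of 7 / 6 / 8 of the same subjects
profiled on an mRNA platform, planted differentially expressed features
with fold changes above 2, planted repressive miRNA-target pairs with a
configured negative Spearman correlation, per-database target predictions
with configurable sensitivity and false-prediction rate, a clinical
gene-set catalog, and companion Ct tables for qPCR-style validation.

Every random draw flows from a single :func:`numpy.random.default_rng`
seed, so one seed yields one byte-identical dataset.

Correlation planting
--------------------
The population Spearman correlation of a planted pair is defined over the
population the screening stage actually samples: subjects profiled on
both platforms in the active UC and control groups (a two-group mixture).
Part of that correlation is contributed by the opposite planted fold
changes; the remainder comes from a shared per-subject latent factor
(severity-like co-variation).  The latent loading is carved out of the
configured noise variance — planted features keep the same marginal
within-group standard deviation as every other feature — and is
calibrated numerically so the mixture Spearman hits the configured value.
If the target is too strong to fit inside the noise budget the latent
variance is added on top instead (with a warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import CATEGORY_PRIORITY, STANDARD_DATABASES, ExpressionMatrix, validate_sample_sheet
from .stats_core import spearman_rho

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_predictions",
    "simulate_gene_sets",
    "simulate_ct_table",
    "evaluate_recovery",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Group sizes mirror the emulated design; dimensions are scaled down
    from the real platforms (~1100 mature-miRNA probe sets, ~20k genes)
    for desk-scale runtime while keeping the paper-like fractions of
    differentially expressed features.
    """

    n_mirna: int = 300
    n_mrna: int = 2000
    # miRNA platform group sizes (active UC / inactive UC / control)
    mirna_group_sizes: tuple[int, int, int] = (10, 7, 10)
    # mRNA platform sizes; subjects are a subset of the miRNA-platform ones
    mrna_group_sizes: tuple[int, int, int] = (7, 6, 8)
    n_de_mirna: int = 20
    n_de_mrna: int = 150
    de_log2fc: float = 1.5
    noise_sd: float = 0.5
    n_planted_pairs: int = 50
    pair_rho: float = -0.85
    db_sensitivity: float = 0.9
    db_false_rate: float = 0.02
    duplicate_probe_fraction: float = 0.05
    catalog_background_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 2 for g in self.mirna_group_sizes + self.mrna_group_sizes):
            raise ValueError("every group needs >= 2 samples")
        if any(m > g for m, g in zip(self.mrna_group_sizes, self.mirna_group_sizes)):
            raise ValueError("mRNA-platform subjects must be a subset of miRNA-platform subjects")
        if not (-1.0 < self.pair_rho < 0.0):
            raise ValueError("pair_rho must lie in (-1, 0)")
        if self.n_planted_pairs > 0 and abs(self.de_log2fc) <= 1.0:
            warnings.warn("planted |log2FC| <= 1: planted features will fail the FC > 2 gate")
        if self.n_planted_pairs > self.n_de_mrna:
            raise ValueError("need at least one distinct DE gene per planted pair")
        if self.n_planted_pairs > 0 and self.n_de_mirna == 0:
            raise ValueError("planted pairs require planted DE miRNAs")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated study."""

    de_mirna: dict[str, int]  # feature id -> direction (+1 up in active, -1 down)
    de_genes: dict[str, int]  # gene symbol -> direction
    pairs: tuple[tuple[str, str], ...]  # planted (mirna_id, gene_symbol)
    pair_rho: float
    annotation: dict[str, str]  # mRNA probe-set id -> gene symbol

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.pairs)


def _mirna_name(i: int) -> str:
    return f"hsa-miR-{1000 + i}-{'5p' if i % 2 == 0 else '3p'}"


def _gene_name(i: int) -> str:
    return f"GENE{i:04d}"


@lru_cache(maxsize=64)
def _calibrate_latent_sd(
    rho_target: float, delta: float, noise_sd: float, n_case: int, n_control: int
) -> float:
    """Latent-factor loading giving the target mixture Spearman.

    Solves, by bisection on a large fixed-seed Monte Carlo population, for
    the loading ``a`` such that x = -delta*g - a*Z + e and
    y = +delta*g + a*Z + e' have Spearman rho_target over a mixture with
    P(case) = n_case/(n_case+n_control).  The idiosyncratic noise is
    reduced to keep each variable's marginal within-group variance at
    noise_sd^2 when possible.
    """
    rng = np.random.default_rng(123456789)
    n = 120_000
    g = rng.random(n) < n_case / (n_case + n_control)
    z = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)

    def mixture_rho(a: float) -> float:
        resid = math.sqrt(max(noise_sd**2 - a * a, 0.0))
        x = -delta * g - a * z + resid * e1
        y = delta * g + a * z + resid * e2
        # Spearman = Pearson of ranks; ties are measure-zero here
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        rx -= rx.mean()
        ry -= ry.mean()
        return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))

    target = rho_target
    lo, hi = 0.0, max(3.0, 3.0 * noise_sd)
    if mixture_rho(lo) <= target:  # group effect alone already reaches it
        return 0.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mixture_rho(mid) > target:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    if a > noise_sd + 1e-9:
        warnings.warn(
            "target pair correlation exceeds the noise budget; "
            "planted features carry extra variance"
        )
    return a


def _subjects(config: SimulationConfig) -> pd.DataFrame:
    groups = ("active_UC", "inactive_UC", "control")
    rows = []
    for label, prefix, n_mi, n_m in zip(
        groups, ("A", "I", "C"), config.mirna_group_sizes, config.mrna_group_sizes
    ):
        for i in range(n_mi):
            rows.append(
                {"subject_id": f"{prefix}{i + 1:02d}", "group": label, "on_mrna": i < n_m}
            )
    return pd.DataFrame(rows)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate the paired expression matrices, sample sheet and truth."""
    rng = np.random.default_rng(config.seed)
    subjects = _subjects(config)
    n_subj = len(subjects)
    active = (subjects["group"] == "active_UC").to_numpy()

    mirna_ids = [_mirna_name(i) for i in range(config.n_mirna)]
    gene_ids = [_gene_name(i) for i in range(config.n_mrna)]

    # planted DE features: alternating up/down directions
    de_mirna = {mirna_ids[i]: (1 if i % 2 == 0 else -1) for i in range(config.n_de_mirna)}
    de_genes = {gene_ids[i]: (1 if i % 2 == 0 else -1) for i in range(config.n_de_mrna)}

    # planted repressive pairs: cycle over DE miRNAs, pick a distinct DE
    # gene of the opposite direction for each
    genes_up = [g for g, d in de_genes.items() if d > 0]
    genes_down = [g for g, d in de_genes.items() if d < 0]
    pairs: list[tuple[str, str]] = []
    de_mirna_ids = list(de_mirna)
    for k in range(config.n_planted_pairs):
        m = de_mirna_ids[k % len(de_mirna_ids)]
        pool = genes_down if de_mirna[m] > 0 else genes_up
        if not pool:
            raise ValueError("not enough DE genes of the required direction for planted pairs")
        pairs.append((m, pool.pop(0)))

    # probe sets: one per gene, plus duplicates for a fraction of genes
    annotation = {f"PS{i:05d}": gene_ids[i] for i in range(config.n_mrna)}
    n_dup = int(round(config.duplicate_probe_fraction * config.n_mrna))
    dup_genes = rng.choice(config.n_mrna, size=n_dup, replace=False) if n_dup else np.array([], int)
    for j, gi in enumerate(np.sort(dup_genes)):
        annotation[f"PS{config.n_mrna + j:05d}_x"] = gene_ids[gi]
    probe_ids = sorted(annotation)

    # one independent per-subject latent factor per planted miRNA, shared
    # with that miRNA's target genes (failures stay uncorrelated across pairs)
    latent_of_mirna = {m: rng.standard_normal(n_subj) for m in dict.fromkeys(m for m, _ in pairs)}
    latent_of_gene = {g: latent_of_mirna[m] for m, g in pairs}
    a = (
        _calibrate_latent_sd(
            config.pair_rho,
            config.de_log2fc,
            config.noise_sd,
            config.mrna_group_sizes[0],
            config.mrna_group_sizes[2],
        )
        if config.n_planted_pairs
        else 0.0
    )
    resid_sd = math.sqrt(max(config.noise_sd**2 - a * a, 0.0))

    def build(
        feature_list: list[str], de_map: dict[str, int], latents: dict[str, np.ndarray]
    ) -> np.ndarray:
        n_feat = len(feature_list)
        baseline = rng.uniform(4.0, 12.0, size=n_feat)
        values = np.empty((n_feat, n_subj))
        for i, feat in enumerate(feature_list):
            direction = de_map.get(feat, 0)
            mean = baseline[i] + direction * config.de_log2fc * active
            z = latents.get(feat)
            if z is not None:
                # latent factor opposes the fold-change direction, so the two
                # members of a pair (opposite DE signs) load on z oppositely
                values[i] = mean - de_map[feat] * a * z + resid_sd * rng.standard_normal(n_subj)
            else:
                values[i] = mean + config.noise_sd * rng.standard_normal(n_subj)
        return values

    # miRNA matrix over all subjects
    mirna_values = build(mirna_ids, de_mirna, latent_of_mirna)
    # gene-level signal, then probe-level copies with independent noise
    gene_values = build(gene_ids, de_genes, latent_of_gene)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    probe_values = np.empty((len(probe_ids), n_subj))
    for k, probe in enumerate(probe_ids):
        gi = gene_index[annotation[probe]]
        if probe.endswith("_x"):
            # duplicate probe: same gene signal, independent measurement noise
            probe_values[k] = gene_values[gi] + 0.2 * rng.standard_normal(n_subj)
        else:
            probe_values[k] = gene_values[gi]

    mirna_samples = [f"{s}_mi" for s in subjects["subject_id"]]
    mirna_expr = ExpressionMatrix(tuple(mirna_ids), tuple(mirna_samples), mirna_values)

    on_mrna = subjects["on_mrna"].to_numpy()
    mrna_samples = [f"{s}_m" for s in subjects.loc[on_mrna, "subject_id"]]
    mrna_expr = ExpressionMatrix(tuple(probe_ids), tuple(mrna_samples), probe_values[:, on_mrna])

    sheet_rows = [
        {"sample_id": f"{r.subject_id}_mi", "subject_id": r.subject_id, "group": r.group, "platform": "miRNA"}
        for r in subjects.itertuples()
    ] + [
        {"sample_id": f"{r.subject_id}_m", "subject_id": r.subject_id, "group": r.group, "platform": "mRNA"}
        for r in subjects.itertuples()
        if r.on_mrna
    ]
    sheet = validate_sample_sheet(pd.DataFrame(sheet_rows))

    truth = SyntheticTruth(
        de_mirna=de_mirna,
        de_genes=de_genes,
        pairs=tuple(pairs),
        pair_rho=config.pair_rho,
        annotation=annotation,
    )
    return mirna_expr, mrna_expr, sheet, truth


def simulate_predictions(
    truth: SyntheticTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-database prediction records for the five standard databases.

    Each planted pair is reported by each database independently with
    probability ``db_sensitivity``; every non-planted (miRNA, gene)
    combination is falsely reported per database with probability
    ``db_false_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    mirna_ids = [_mirna_name(i) for i in range(config.n_mirna)]
    gene_ids = [_gene_name(i) for i in range(config.n_mrna)]
    planted = truth.pair_set
    rows: list[tuple[str, str, str]] = []
    for db in STANDARD_DATABASES:
        for m, g in truth.pairs:
            if rng.random() < config.db_sensitivity:
                rows.append((m, g, db))
        hits = np.nonzero(rng.random((config.n_mirna, config.n_mrna)) < config.db_false_rate)
        for mi, gi in zip(*hits):
            pair = (mirna_ids[mi], gene_ids[gi])
            if pair not in planted:
                rows.append((*pair, db))
    return pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "database"])


def simulate_gene_sets(
    truth: SyntheticTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, frozenset[str]]:
    """Clinical gene-set catalog containing every planted target gene.

    Planted target genes are distributed round-robin over the four
    clinical categories; a background fraction of the remaining genes is
    assigned to random categories so the filter discards most non-planted
    genes without deciding recovery by itself.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    catalog: dict[str, set[str]] = {c: set() for c in CATEGORY_PRIORITY}
    planted_genes = sorted({g for _, g in truth.pairs})
    for i, gene in enumerate(planted_genes):
        catalog[CATEGORY_PRIORITY[i % 4]].add(gene)
    others = [
        _gene_name(i) for i in range(config.n_mrna) if _gene_name(i) not in set(planted_genes)
    ]
    for gene in others:
        if rng.random() < config.catalog_background_fraction:
            catalog[CATEGORY_PRIORITY[rng.integers(4)]].add(gene)
    return {c: frozenset(g) for c, g in catalog.items() if g}


def simulate_ct_table(
    expr: ExpressionMatrix,
    features: list[str],
    rng: np.random.Generator,
    ct_noise_sd: float = 0.1,
    reference_ct: float = 20.0,
    ct_offset: float = 32.0,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Ct tables consistent with an expression matrix.

    Inverse-transforms log2 expression into cycle-threshold space
    (ct_target = ct_offset - log2 expression, plus measurement noise per
    replicate); the reference assay Ct is constant.  Higher expression
    means fewer cycles, as in a real instrument.
    """
    idx = {f: i for i, f in enumerate(expr.feature_ids)}
    rows = []
    for feat in features:
        values = expr.values[idx[feat]]
        for j, sample in enumerate(expr.sample_ids):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sample,
                        "feature": feat,
                        "ct_target": ct_offset - values[j] + ct_noise_sd * rng.standard_normal(),
                        "ct_reference": reference_ct,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def evaluate_recovery(
    reported_pairs: pd.DataFrame, truth: SyntheticTruth
) -> tuple[float, float | None]:
    """Sensitivity and precision of a reported pair list against truth.

    Precision is ``None`` (undefined) when nothing was reported.
    """
    planted = truth.pair_set
    reported = set(zip(reported_pairs["mirna_id"], reported_pairs["gene_symbol"]))
    if not planted:
        raise ValueError("truth contains no planted pairs")
    hits = len(reported & planted)
    sensitivity = hits / len(planted)
    precision = hits / len(reported) if reported else None
    return sensitivity, precision


def simulate_study(config: SimulationConfig) -> dict:
    """One call producing every input the pipeline consumes, plus truth."""
    mirna_expr, mrna_expr, sheet, truth = simulate_expression(config)
    rng = np.random.default_rng(config.seed + 1)
    predictions = simulate_predictions(truth, config, rng)
    gene_sets = simulate_gene_sets(truth, config, rng)
    validation_features = sorted({m for m, _ in truth.pairs})[:5]
    ct = simulate_ct_table(mirna_expr, validation_features, rng)
    return {
        "config": config,
        "mirna_expr": mirna_expr,
        "mrna_expr": mrna_expr,
        "sheet": sheet,
        "truth": truth,
        "predictions": predictions,
        "gene_sets": gene_sets,
        "ct": ct,
    }
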