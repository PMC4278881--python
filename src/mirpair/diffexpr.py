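"""Two-group differential expression with an empirical-Bayes moderated t.

The model is the standard microarray one: per feature, a two-sample
comparison of log2 intensities with pooled residual variance s^2 on
``df = nA + nB - 2`` degrees of freedom.  Per-feature variances are shrunk
toward a common prior by empirical Bayes: assuming s0^2 * chi^2 scaling,

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

with the prior degrees of freedom ``d0`` and prior variance ``s0^2``
estimated by the method of moments on log s^2 (Smyth-style fit of a scaled
F distribution).  The moderated t refers log2FC / (s_tilde * sqrt(1/nA +
1/nB)) to a t distribution with ``d0 + df`` degrees of freedom.

A feature is called biologically significant when the linear fold change
exceeds 2 (|log2FC| > 1) and the Benjamini-Hochberg FDR is below 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix
from .stats_core import bh_adjust, rank_average_ties

__all__ = [
    "ModeratedFit",
    "quantile_normalize",
    "fit_two_group",
    "moderate_variances",
    "de_table",
    "venn_overlap",
]


@dataclass(frozen=True)
class ModeratedFit:
    """Empirical-Bayes variance-moderation hyperparameters and posteriors."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior variance
    s_tilde_sq: np.ndarray  # posterior variances, one per feature


@dataclass(frozen=True)
class TwoGroupFit:
    """Per-feature summaries of a two-group comparison (group A minus B)."""

    feature_ids: tuple[str, ...]
    log2fc: np.ndarray
    s_sq: np.ndarray
    df_residual: int
    avg_expr: np.ndarray
    n_a: int
    n_b: int


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the same empirical distribution.

    The target distribution is the row-wise mean of the sorted columns.
    Tied values within a column receive the mean of the reference values
    their ranks span, so the operation is well defined and idempotent.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile normalization of a single sample is the identity")
        return matrix
    values = matrix.values
    n = matrix.n_features
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(matrix.n_samples):
        ranks = rank_average_ties(values[:, j]).ranks
        # average ranks may be half-integers; interpolate the reference
        out[:, j] = np.interp(ranks, grid, reference)
    return ExpressionMatrix(matrix.feature_ids, matrix.sample_ids, out)


def _group_samples(sheet: pd.DataFrame, group: str, sample_ids: tuple[str, ...]) -> list[str]:
    present = set(sample_ids)
    return [s for s in sheet.loc[sheet["group"] == group, "sample_id"] if s in present]


def fit_two_group(
    matrix: ExpressionMatrix,
    sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> TwoGroupFit:
    """Per-feature mean difference and pooled variance for A vs B."""
    samples_a = _group_samples(sheet, group_a, matrix.sample_ids)
    samples_b = _group_samples(sheet, group_b, matrix.sample_ids)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"both groups need >= 2 samples on this platform "
            f"({group_a}: {len(samples_a)}, {group_b}: {len(samples_b)})"
        )
    a = matrix.subset_samples(samples_a).values
    b = matrix.subset_samples(samples_b).values
    n_a, n_b = a.shape[1], b.shape[1]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss_a = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_b = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_a + n_b - 2
    return TwoGroupFit(
        feature_ids=matrix.feature_ids,
        log2fc=log2fc,
        s_sq=(ss_a + ss_b) / df,
        df_residual=df,
        avg_expr=np.concatenate([a, b], axis=1).mean(axis=1),
        n_a=n_a,
        n_b=n_b,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def moderate_variances(
    s_sq: np.ndarray,
    df: int,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedFit:
    """Estimate (d0, s0^2) and return the shrunken posterior variances.

    When ``d0`` (and optionally ``s0_sq``) is supplied the hyperparameter
    estimation is skipped and only the shrinkage formula is applied
    (useful for the no-shrinkage d0 = 0 and complete-pooling d0 = inf
    limits).  Features with zero sample variance are excluded from moment
    estimation but still receive a posterior variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if d0 is None:
        if s_sq.size < 10:
            raise ValueError("need >= 10 features to estimate hyperparameters")
        positive = s_sq[s_sq > 0]
        if positive.size < 10:
            raise ValueError("too few positive variances to estimate hyperparameters")
        z = np.log(positive)
        e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
        e_mean = float(e.mean())
        e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
        if e_var > 0:
            d0 = 2.0 * _trigamma_inverse(e_var)
            s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        else:
            if e_var < 0 and abs(e_var) > 1e-12:
                warnings.warn("moment estimate of d0 is non-positive; using d0 = inf")
            d0 = math.inf
            s0_sq = math.exp(e_mean)
    elif s0_sq is None:
        positive = s_sq[s_sq > 0]
        s0_sq = float(np.exp(np.log(positive).mean())) if positive.size else 1.0
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
    elif d0 == 0:
        s_tilde_sq = s_sq.copy()
    else:
        s_tilde_sq = (d0 * s0_sq + df * s_sq) / (d0 + df)
    return ModeratedFit(d0=float(d0), s0_sq=float(s0_sq), s_tilde_sq=s_tilde_sq)


def de_table(
    fit: TwoGroupFit,
    moderated: ModeratedFit,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated-t differential expression table with significance flags.

    Columns: feature_id, log2FC, FC (signed linear fold change), avg_expr,
    t, p, fdr, significant.  ``significant`` requires both
    |log2FC| > log2(fc_threshold) and fdr < fdr_threshold.
    """
    if moderated.s_tilde_sq.shape[0] != len(fit.feature_ids):
        raise ValueError("fit and moderated variances are not aligned")
    se = np.sqrt(moderated.s_tilde_sq * (1.0 / fit.n_a + 1.0 / fit.n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.log2fc / se, np.where(fit.log2fc == 0, 0.0, np.inf * np.sign(fit.log2fc)))
    df_total = moderated.d0 + fit.df_residual
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_adjust(p)
    log2_cut = math.log2(fc_threshold)
    table = pd.DataFrame(
        {
            "feature_id": list(fit.feature_ids),
            "log2FC": fit.log2fc,
            "FC": np.sign(fit.log2fc) * 2.0 ** np.abs(fit.log2fc),
            "avg_expr": fit.avg_expr,
            "t": t,
            "p": p,
            "fdr": fdr,
        }
    )
    table["significant"] = (np.abs(table["log2FC"]) > log2_cut) & (table["fdr"] < fdr_threshold)
    return table


def venn_overlap(de_a: pd.DataFrame, de_b: pd.DataFrame) -> dict[str, int]:
    """Direction-matched overlap of two significant feature sets.

    Returns counts of features significant in both tables with the same
    fold-change direction, split into up- and downregulated.
    """
    def _directions(table: pd.DataFrame) -> dict[str, int]:
        sig = table[table["significant"]]
        return {f: (1 if fc > 0 else -1) for f, fc in zip(sig["feature_id"], sig["log2FC"])}

    dir_a = _directions(de_a)
    dir_b = _directions(de_b)
    up = sum(1 for f, d in dir_a.items() if d > 0 and dir_b.get(f) == 1)
    down = sum(1 for f, d in dir_a.items() if d < 0 and dir_b.get(f) == -1)
    return {"total": up + down, "up": up, "down": down}
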