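"""qRT-PCR style validation: 2^-ddCt quantification and group comparison.

Relative quantification normalizes each sample's target Ct to a reference
assay (dCt = Ct_target - Ct_reference) and to the mean dCt of a calibrator
group (ddCt), so the relative quantity rq = 2^-ddCt equals 1 on average
(geometrically) in the calibrator group.  Group differences are assessed
with the Mann-Whitney U test, and fold changes are displayed with the
signed convention common in the field: a ratio r < 1 is written as -1/r.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .stats_core import TestResult, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "relative_quantity_ddct",
    "qpcr_group_test",
    "signed_fold_change",
    "concordance_check",
]


def relative_quantity_ddct(
    ct: pd.DataFrame,
    calibrator_group: str,
    sheet: pd.DataFrame,
) -> pd.DataFrame:
    """2^-ddCt relative quantities per sample and assay.

    Replicate Cts are averaged (arithmetic mean) per sample before dCt is
    formed; ddCt subtracts the calibrator group's mean dCt per assay.
    Samples missing a reference Ct are dropped with a log entry.  Returns
    columns sample_id, feature, rq.
    """
    missing_ref = ct["ct_reference"].isna()
    if missing_ref.any():
        logger.info("dropping %d Ct rows without a reference Ct", int(missing_ref.sum()))
        ct = ct[~missing_ref]
    per_sample = (
        ct.groupby(["feature", "sample_id"], as_index=False)[["ct_target", "ct_reference"]].mean()
    )
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))
    per_sample["group"] = per_sample["sample_id"].map(group_of)
    rows = []
    for feature, sub in per_sample.groupby("feature"):
        calib = sub[sub["group"] == calibrator_group]
        if calib.empty:
            raise ValueError(f"calibrator group {calibrator_group!r} has no samples for {feature}")
        calib_mean = calib["dct"].mean()
        for r in sub.itertuples():
            rows.append(
                {"sample_id": r.sample_id, "feature": feature, "rq": 2.0 ** -(r.dct - calib_mean)}
            )
    return pd.DataFrame(rows, columns=["sample_id", "feature", "rq"])


def signed_fold_change(ratio: float) -> float:
    """Display convention for fold changes: ratios below 1 become -1/ratio.

    An involution up to reciprocal: signed(1/r) == -signed(r).
    """
    if ratio <= 0 or not math.isfinite(ratio):
        raise ValueError("ratio must be positive and finite")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def qpcr_group_test(
    rq: pd.DataFrame,
    group_a: str,
    group_b: str,
    sheet: pd.DataFrame,
    feature: str | None = None,
) -> tuple[TestResult, float]:
    """Mann-Whitney comparison of per-sample relative quantities.

    Returns the test result and the fold change of group A over group B
    (ratio of group means under the signed display convention).  When the
    rq table holds several assays, ``feature`` selects one.
    """
    table = rq if feature is None else rq[rq["feature"] == feature]
    if feature is None and table["feature"].nunique() > 1:
        raise ValueError("rq table holds several assays; pass feature=")
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))
    groups = table["sample_id"].map(group_of)
    a = table.loc[groups == group_a, "rq"].to_numpy(dtype=float)
    b = table.loc[groups == group_b, "rq"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"both groups must be represented ({group_a}: {a.size}, {group_b}: {b.size})")
    return mann_whitney(a, b), signed_fold_change(float(a.mean() / b.mean()))


def concordance_check(qpcr_fc: float, array_log2fc: float) -> str:
    """'concordant' when the qPCR and array fold changes agree in direction.

    The qPCR fold change uses the signed convention (|fc| >= 1, sign =
    direction); the array value is a log2 fold change.  Zero either way is
    rejected: the direction is undefined.
    """
    if not (math.isfinite(qpcr_fc) and math.isfinite(array_log2fc)):
        raise ValueError("fold changes must be finite")
    if qpcr_fc == 0 or array_log2fc == 0:
        raise ValueError("zero fold change has no direction")
    return "concordant" if (qpcr_fc > 0) == (array_log2fc > 0) else "discordant"
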