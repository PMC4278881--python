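"""Typed containers and TSV readers/writers for every pipeline format.

All on-disk formats are plain tab-separated text:

* expression matrix — header row of sample IDs, first column ``feature_id``,
  remaining cells log2 intensities;
* sample sheet — columns ``sample_id``, ``subject_id``, ``group``,
  ``platform``;
* prediction table — columns ``mirna_id``, ``gene_symbol``, ``database``;
* gene-set catalog — columns ``category``, ``gene_symbol``;
* Ct table — columns ``sample_id``, ``feature``, ``ct_target``,
  ``ct_reference``, ``replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GROUPS = ("active_UC", "inactive_UC", "control", "CDc", "IC")
PLATFORMS = ("miRNA", "mRNA")
DATABASES = ("miRanda", "miRDB", "miRWalk", "RNA22", "TargetScan", "DianaMicroT")
STANDARD_DATABASES = ("miRanda", "miRDB", "miRWalk", "RNA22", "TargetScan")
ALTERNATIVE_DATABASES = ("miRanda", "miRWalk", "DianaMicroT")
CATEGORIES = ("UC_susceptibility", "AMP", "CAM", "barrier")
# display priority when a gene sits in several clinical categories
CATEGORY_PRIORITY = ("UC_susceptibility", "barrier", "CAM", "AMP")
CATEGORY_LABELS = {
    "UC_susceptibility": "UC susceptibility gene",
    "barrier": "Barrier gene",
    "CAM": "Cell adhesion molecule",
    "AMP": "Anti-microbial peptide",
}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values, features x samples."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match feature/sample ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite (no missing values)")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        object.__setattr__(self, "values", v)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            feature_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in wanted]
        return ExpressionMatrix(self.feature_ids, tuple(wanted), self.values[:, cols])


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    return ExpressionMatrix.from_frame(frame)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.6f")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "subject_id", "group", "platform"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad_groups = set(sheet["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    bad_platforms = set(sheet["platform"]) - set(PLATFORMS)
    if bad_platforms:
        raise ValueError(f"unknown platforms: {sorted(bad_platforms)}")
    for platform, sub in sheet.groupby("platform"):
        if sub["sample_id"].duplicated().any():
            raise ValueError(f"duplicate sample_ids on platform {platform}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype=str)
    return validate_predictions(records)


def validate_predictions(records: pd.DataFrame) -> pd.DataFrame:
    required = {"mirna_id", "gene_symbol", "database"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    unknown = set(records["database"]) - set(DATABASES)
    if unknown:
        raise ValueError(f"unknown prediction databases: {sorted(unknown)}")
    return records.drop_duplicates(subset=["mirna_id", "gene_symbol", "database"])


def write_predictions(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"category", "gene_symbol"}
    if required - set(frame.columns):
        raise ValueError("gene-set table needs columns category, gene_symbol")
    return validate_gene_sets(
        {cat: frozenset(sub["gene_symbol"]) for cat, sub in frame.groupby("category")}
    )


def validate_gene_sets(catalog: Mapping[str, Iterable[str]]) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for cat, genes in catalog.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown clinical category: {cat!r}")
        genes = frozenset(str(g) for g in genes)
        if any(not g for g in genes):
            raise ValueError(f"empty gene symbol in category {cat}")
        out[cat] = genes
    return out


def write_gene_sets(catalog: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"category": cat, "gene_symbol": gene}
        for cat in sorted(catalog)
        for gene in sorted(catalog[cat])
    ]
    pd.DataFrame(rows, columns=["category", "gene_symbol"]).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, str]:
    """Probe-set -> gene-symbol map (TSV columns probe_id, gene_symbol)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if {"probe_id", "gene_symbol"} - set(frame.columns):
        raise ValueError("annotation table needs columns probe_id, gene_symbol")
    if frame["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_ids in annotation table")
    return dict(zip(frame["probe_id"], frame["gene_symbol"]))


def write_annotation(annotation: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(annotation.items()), columns=["probe_id", "gene_symbol"]
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    required = {"sample_id", "feature", "ct_target", "ct_reference", "replicate"}
    if required - set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    for col in ("ct_target", "ct_reference"):
        vals = ct[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"{col} must be positive and finite")
    return ct


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_geo_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Load a GEO series-matrix TSV export (metadata lines start with '!').

    Convenience for users who fetch the deposited series themselves; not
    part of the simulated pipeline surface.
    """
    rows: list[str] = []
    with open(path) as handle:
        in_table = False
        for line in handle:
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if in_table and line.strip():
                rows.append(line)
            elif not line.startswith("!") and line.strip() and not in_table:
                rows.append(line)
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(rows)), sep="\t", index_col=0)
    frame.columns = [str(c).strip('"') for c in frame.columns]
    frame.index = [str(i).strip('"') for i in frame.index]
    frame = frame.dropna(how="any")
    return ExpressionMatrix.from_frame(frame)
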