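"""Expression-matrix IO, validation, normalization, filtering and class summaries.

All tabular inputs are plain TSV (tab separator, UTF-8, no quoting):

* count matrix — first column ``feature_id``, remaining columns are sample ids;
* sample sheet — columns ``sample_id``, ``mouse_id``, ``age_months``, ``fraction``;
* feature sheet — columns ``feature_id``, ``rna_class``.

Matrices are oriented features-in-rows throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_RNA_CLASSES",
    "ValidationError",
    "ExpressionMatrix",
    "read_expression",
    "read_sample_sheet",
    "read_feature_sheet",
    "normalize_rpm",
    "filter_expressed",
    "class_summary",
    "ClassSummary",
]

#: Default vocabulary of the 10 small-RNA classes. Nine are canonical names;
#: the class vocabulary is configurable everywhere it is consumed.
DEFAULT_RNA_CLASSES: tuple[str, ...] = (
    "miRNA",
    "piRNA",
    "tRNA",
    "rRNA",
    "snRNA",
    "snoRNA",
    "scaRNA",
    "lincRNA",
    "circRNA",
    "misc_RNA",
)

FRACTIONS = ("EV", "FC")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Non-negative feature x sample expression matrix.

    Parameters
    ----------
    data :
        DataFrame with feature ids as index and sample ids as columns.
    unit :
        ``"raw_counts"`` or ``"rpm"``.
    """

    data: pd.DataFrame
    unit: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.unit not in ("raw_counts", "rpm"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (vals < 0).any():
            raise ValidationError("expression matrix contains negative values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], unit=self.unit)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise ValidationError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(feature_ids), :], unit=self.unit)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mouse_id": str, "fraction": str})
    required = {"sample_id", "mouse_id", "age_months", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    if (df["age_months"] <= 0).any():
        raise ValidationError("age_months must be positive")
    bad = set(df["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValidationError(f"unknown fraction labels: {sorted(bad)} (expected {FRACTIONS})")
    return df


def read_feature_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature_id", "rna_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"feature sheet missing columns: {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        raise ValidationError("duplicate feature_id in feature sheet")
    if df["rna_class"].isna().any() or (df["rna_class"].str.len() == 0).any():
        raise ValidationError("empty rna_class annotation")
    return df


def validate_cohort(
    matrix: ExpressionMatrix, samples: pd.DataFrame, features: pd.DataFrame
) -> None:
    """Cross-validate matrix ids against the annotation sheets."""
    sheet_samples = set(samples["sample_id"])
    for s in matrix.sample_ids:
        if s not in sheet_samples:
            raise ValidationError(f"sample {s!r} in matrix absent from sample sheet")
    sheet_features = set(features["feature_id"])
    for f in matrix.feature_ids:
        if f not in sheet_features:
            raise ValidationError(f"feature {f!r} in matrix absent from feature sheet")


def read_expression(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    feature_sheet_path: str | Path,
    unit: str = "raw_counts",
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a count matrix with its annotation sheets and cross-validate.

    Returns
    -------
    tuple of (ExpressionMatrix, sample sheet DataFrame, feature sheet DataFrame).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    matrix = ExpressionMatrix(raw, unit=unit)
    samples = read_sample_sheet(sample_sheet_path)
    features = read_feature_sheet(feature_sheet_path)
    validate_cohort(matrix, samples, features)
    return matrix, samples, features


def normalize_rpm(x: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to reads-per-million (column sums of 1e6).

    Library size is the column sum over all features present in the matrix;
    normalization happens once on the full matrix, before any class subsetting.
    """
    if x.unit != "raw_counts":
        raise ValidationError("normalize_rpm expects raw counts")
    colsums = x.data.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample(s): {zero.index.tolist()}")
    rpm = x.data.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(rpm, unit="rpm")


def filter_expressed(
    x: ExpressionMatrix, min_rpm: float = 5.0, min_samples: int = 1
) -> ExpressionMatrix:
    """Keep features with >= ``min_rpm`` RPM in >= ``min_samples`` samples.

    Thresholds are inclusive ("at least 5 reads per million in at least one
    sample"). Idempotent; the sample set is unchanged.
    """
    if x.unit != "rpm":
        raise ValidationError("filter_expressed expects an RPM matrix")
    keep = (x.data >= min_rpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(x.data.loc[keep], unit="rpm")


@dataclass
class ClassSummary:
    """Per-RNA-class summaries across the two plasma fractions.

    Attributes
    ----------
    read_share :
        DataFrame class x fraction; share of total reads, sums to 1 per fraction.
    detection :
        Long DataFrame with columns rna_class, fraction, threshold, detected
        (fraction of class members whose maximum RPM in that fraction is
        >= threshold); monotone non-increasing in threshold.
    overlap :
        DataFrame per class with columns both, ev_only, fc_only (counts of
        features passing the expression filter in each fraction).
    """

    read_share: pd.DataFrame
    detection: pd.DataFrame
    overlap: pd.DataFrame
    thresholds: tuple[float, ...] = field(default_factory=tuple)


def class_summary(
    x: ExpressionMatrix,
    features: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: Sequence[float] = (0, 1, 5, 10, 50, 100),
    min_rpm: float = 5.0,
) -> ClassSummary:
    """Compute read shares, detection curves and EV/fc overlap per RNA class.

    "Detected" for the overlap counts means passing :func:`filter_expressed`
    within that fraction's samples — the only threshold stated anywhere.
    """
    if x.unit != "rpm":
        raise ValidationError("class_summary expects an RPM matrix")
    classes = features.set_index("feature_id")["rna_class"]
    class_vocab = sorted(classes.loc[x.feature_ids].unique())
    if not class_vocab:
        raise ValidationError("empty class vocabulary")
    sample_fraction = samples.set_index("sample_id")["fraction"]

    share_rows = {}
    det_rows = []
    overlap_detected: dict[str, pd.Index] = {}
    for frac in FRACTIONS:
        cols = [s for s in x.sample_ids if sample_fraction.get(s) == frac]
        if not cols:
            continue
        sub = x.data[cols]
        totals = sub.groupby(classes.loc[x.feature_ids].values).sum().sum(axis=1)
        total_reads = totals.sum()
        share_rows[frac] = totals / total_reads if total_reads > 0 else totals * np.nan
        feat_max = sub.max(axis=1)
        for cls in class_vocab:
            in_cls = classes.loc[x.feature_ids] == cls
            n_cls = int(in_cls.sum())
            for thr in thresholds:
                det = float((feat_max[in_cls.values] >= thr).mean()) if n_cls else np.nan
                det_rows.append(
                    {"rna_class": cls, "fraction": frac, "threshold": thr, "detected": det}
                )
        detected = feat_max.index[(sub >= min_rpm).any(axis=1)]
        overlap_detected[frac] = detected

    read_share = pd.DataFrame(share_rows).reindex(class_vocab).fillna(0.0)
    detection = pd.DataFrame(det_rows)

    ev = set(overlap_detected.get("EV", []))
    fc = set(overlap_detected.get("FC", []))
    rows = []
    for cls in class_vocab:
        members = set(classes.index[classes == cls]) & set(x.feature_ids)
        rows.append(
            {
                "rna_class": cls,
                "both": len(members & ev & fc),
                "ev_only": len(members & ev - fc),
                "fc_only": len(members & fc - ev),
            }
        )
    overlap = pd.DataFrame(rows).set_index("rna_class")
    return ClassSummary(
        read_share=read_share,
        detection=detection,
        overlap=overlap,
        thresholds=tuple(thresholds),
    )
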