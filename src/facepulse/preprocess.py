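"""Dataset cleanup: missing-value removal, outlier removal, undersampling.

The pipeline order is fixed — drop rows with missing features, remove
outliers, then undersample the majority class — so that dropped rows can
never unbalance the final classes. Outlier fences and the undersampling pool
are computed over the whole dataset.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ClassMissingError, EmptyDatasetError
from .labeling import LabeledDataset

__all__ = ["PreprocessReport", "drop_missing", "remove_outliers", "undersample", "preprocess"]

#: Columns that identify rows rather than describe them; excluded from
#: missing/outlier screening and from the model feature matrix.
ID_COLUMNS = ("frame",)


@dataclass
class PreprocessReport:
    """Row bookkeeping for one preprocessing run (in = out + dropped per step)."""

    rows_in: int = 0
    rows_dropped_missing: int = 0
    rows_dropped_outlier: int = 0
    positives_before: int = 0
    negatives_before: int = 0
    positives_after: int = 0
    negatives_after: int = 0
    outlier_mode: str = ""
    seed: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ID_COLUMNS]


def _subset(dataset: LabeledDataset, keep: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        features=dataset.features.loc[keep].reset_index(drop=True),
        labels=dataset.labels[keep],
        provenance=dataset.provenance[keep],
        fps=dataset.fps,
        conventions=dict(dataset.conventions),
    )


def drop_missing(dataset: LabeledDataset) -> tuple[LabeledDataset, PreprocessReport]:
    """Remove rows containing any missing feature value, preserving order."""
    report = PreprocessReport(rows_in=len(dataset.features))
    keep = dataset.features[_feature_columns(dataset.features)].notna().all(axis=1).to_numpy()
    report.rows_dropped_missing = int((~keep).sum())
    if not keep.any():
        raise EmptyDatasetError("all rows contain missing values")
    return _subset(dataset, keep), report


def remove_outliers(
    dataset: LabeledDataset, mode: str = "tukey"
) -> tuple[LabeledDataset, PreprocessReport]:
    """Drop rows with any feature outside its per-feature fence.

    ``tukey`` (default) fences at ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``;
    ``literal_quartile`` applies the strict ``[Q1, Q3]`` band (removes about
    half the rows per feature — retained for fidelity experiments only).
    Quartiles are computed per feature over the entire dataset.
    """
    if mode not in ("tukey", "literal_quartile"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    df = dataset.features[_feature_columns(dataset.features)]
    if len(df) < 4:
        raise ValueError("remove_outliers requires at least 4 rows")
    q1 = df.quantile(0.25, interpolation="linear")
    q3 = df.quantile(0.75, interpolation="linear")
    if mode == "tukey":
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        lo, hi = q1, q3
    keep = ((df >= lo) & (df <= hi)).all(axis=1).to_numpy()
    report = PreprocessReport(
        rows_in=len(df), rows_dropped_outlier=int((~keep).sum()), outlier_mode=mode
    )
    if not keep.any():
        raise EmptyDatasetError("outlier removal dropped every row")
    return _subset(dataset, keep), report


def undersample(dataset: LabeledDataset, seed: int) -> tuple[LabeledDataset, PreprocessReport]:
    """Randomly subsample the majority class (without replacement) to the minority count.

    The minority class is untouched; row order is preserved; the selection is
    reproducible under ``seed``.
    """
    labels = dataset.labels
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassMissingError("undersampling requires both classes present")
    report = PreprocessReport(
        rows_in=len(labels),
        positives_before=n_pos,
        negatives_before=n_neg,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    majority = 0 if n_neg > n_pos else 1
    target = min(n_pos, n_neg)
    maj_idx = np.flatnonzero(labels == majority)
    keep_idx = np.sort(
        np.concatenate(
            [np.flatnonzero(labels != majority), rng.choice(maj_idx, target, replace=False)]
        )
    )
    keep = np.zeros(len(labels), dtype=bool)
    keep[keep_idx] = True
    out = _subset(dataset, keep)
    report.positives_after = int((out.labels == 1).sum())
    report.negatives_after = int((out.labels == 0).sum())
    return out, report


def preprocess(
    dataset: LabeledDataset, seed: int, outlier_mode: str = "tukey"
) -> tuple[LabeledDataset, PreprocessReport]:
    """Run the fixed pipeline: drop_missing -> remove_outliers -> undersample."""
    step1, rep1 = drop_missing(dataset)
    step2, rep2 = remove_outliers(step1, mode=outlier_mode)
    out, rep3 = undersample(step2, seed=seed)
    return out, PreprocessReport(
        rows_in=rep1.rows_in,
        rows_dropped_missing=rep1.rows_dropped_missing,
        rows_dropped_outlier=rep2.rows_dropped_outlier,
        positives_before=rep3.positives_before,
        negatives_before=rep3.negatives_before,
        positives_after=rep3.positives_after,
        negatives_after=rep3.negatives_after,
        outlier_mode=outlier_mode,
        seed=seed,
    )
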