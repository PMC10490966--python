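"""Confusion-matrix accuracy assessment: overall, producer's/user's, kappa.

Orientation convention: reference classes in rows, mapped classes in columns.
Producer's accuracy for class i is therefore the diagonal over the row sum
(recall against reference data) and user's accuracy the diagonal over the
column sum (precision of mapped labels). Classes absent from both sides are
dropped, which keeps the kappa denominator meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene import ClassMap, GroundTruthSet


@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # r x r, rows = reference, cols = mapped
    class_codes: list[int]      # order shared by rows and columns

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if not np.issubdtype(self.counts.dtype, np.integer) or self.counts.min() < 0:
            raise ValueError("confusion-matrix counts must be nonnegative integers")
        if len(self.class_codes) != self.counts.shape[0]:
            raise ValueError("class_codes length must match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:  # reference totals n_i
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:  # mapped totals n_j
        return self.counts.sum(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_codes, columns=self.class_codes)


def build_confusion(class_map: ClassMap, truth: GroundTruthSet) -> ConfusionMatrix:
    """Cross-tabulate reference labels against mapped labels at truth points."""
    if len(truth) == 0:
        raise ValueError("empty ground-truth set")
    rows, cols, ref = truth.rows, truth.cols, truth.labels
    shape = class_map.shape
    if np.any((rows < 0) | (rows >= shape[0]) | (cols < 0) | (cols >= shape[1])):
        raise ValueError("ground-truth point outside the grid")
    mapped = class_map.classes[rows, cols]
    if np.any(mapped == 0):
        raise ValueError("ground-truth point falls on map nodata")
    codes = sorted(set(ref.tolist()) | set(mapped.tolist()))
    idx = {c: i for i, c in enumerate(codes)}
    r = len(codes)
    counts = np.zeros((r, r), dtype=np.int64)
    for a, b in zip(ref, mapped):
        counts[idx[int(a)], idx[int(b)]] += 1
    return ConfusionMatrix(counts, codes)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correctly mapped reference points, Σ X_ii / M."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty (M = 0)")
    return float(cm.diagonal.sum() / cm.total)


def producers_users_accuracy(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class producer's (X_ii/n_i) and user's (X_jj/n_j) accuracy.

    NaN where the corresponding reference row or mapped column is empty.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty (M = 0)")
    diag = cm.diagonal.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(cm.row_sums > 0, diag / cm.row_sums, np.nan)
        ua = np.where(cm.col_sums > 0, diag / cm.col_sums, np.nan)
    return pd.DataFrame({"producers": pa, "users": ua}, index=cm.class_codes)


@dataclass
class KappaResult:
    value: float | None           # None when the denominator degenerates
    agreement: str                # "strong" (>0.80), "moderate" (0.40-0.80), "poor" (<0.40)


def _agreement_band(k: float) -> str:
    if k > 0.80:
        return "strong"
    if k >= 0.40:
        return "moderate"
    return "poor"


def kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement K = (M·ΣX_ii − Σn_i·n_j) / (M² − Σn_i·n_j).

    Returns an explicit undefined result when M² = Σ n_i·n_j (e.g. a single
    nonempty class), where chance agreement is total and K is 0/0.
    """
    m = cm.total
    if m == 0:
        raise ValueError("confusion matrix is empty (M = 0)")
    chance = float(np.dot(cm.row_sums, cm.col_sums))
    denom = m * m - chance
    if math.isclose(denom, 0.0, abs_tol=1e-12):
        return KappaResult(None, "undefined")
    k = (m * float(cm.diagonal.sum()) - chance) / denom
    return KappaResult(k, _agreement_band(k))


def accuracy_report(cm: ConfusionMatrix) -> dict:
    """Bundle OA, kappa and per-class accuracies into a JSON-friendly dict."""
    pu = producers_users_accuracy(cm)
    kr = kappa(cm)
    return {
        "n_points": cm.total,
        "overall_accuracy": overall_accuracy(cm),
        "kappa": kr.value,
        "kappa_agreement": kr.agreement,
        "per_class": {
            str(code): {
                "producers": None if np.isnan(pu.loc[code, "producers"]) else float(pu.loc[code, "producers"]),
                "users": None if np.isnan(pu.loc[code, "users"]) else float(pu.loc[code, "users"]),
            }
            for code in cm.class_codes
        },
    }
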