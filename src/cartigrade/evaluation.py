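"""Metrics and summary statistics used throughout the pipeline.

Model performance is reported as Spearman rank correlation ρ (robust to
monotone nonlinearity between predicted and true degeneration), RMSE in
reference units, and — for the poor-contact classifier — accuracy and
the F1-score of the outlier class.  Summaries across cross-validation
iterations use median (interquartile range): medians are preferred over
means because single poorly predicted cadavers otherwise dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .spectral_data import CartigradeError

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(CartigradeError):
    """Rank correlation is undefined (constant input)."""


@dataclass(frozen=True)
class EvaluationResult:
    """Regression-performance triple for one evaluation set."""

    rho: float
    rho_p: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be ≥ 0")


def spearman(pred, ref, exact: bool = False) -> tuple[float, float]:
    """Spearman ρ with mid-rank ties and an asymptotic-t p-value.

    ``exact=True`` computes a permutation p-value by full enumeration
    (only for n ≤ 10).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 2:
        raise ValueError("pred and ref must be equal-length vectors with n ≥ 2")
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        raise UndefinedCorrelationError("constant input: Spearman ρ undefined")
    rho, p = stats.spearmanr(pred, ref)
    if exact:
        if pred.size > 10:
            raise ValueError("exact permutation p only supported for n ≤ 10")
        ref_rank = stats.rankdata(ref)
        observed = abs(rho)
        count, total = 0, 0
        for perm in permutations(stats.rankdata(pred)):
            r = stats.spearmanr(perm, ref_rank).statistic
            count += abs(r) >= observed - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def rmse(pred, ref) -> float:
    """Root-mean-square error in reference units."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size < 1:
        raise ValueError("pred and ref must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def evaluate_predictions(pred, ref) -> EvaluationResult:
    rho, p = spearman(pred, ref)
    return EvaluationResult(rho=rho, rho_p=p, rmse=rmse(pred, ref), n=len(np.asarray(pred)))


def classification_metrics(true_labels, pred_labels) -> tuple[float, float]:
    """Accuracy and outlier-class F1 for binary labels.

    With no positives anywhere (no true outliers and none predicted) F1
    is reported as 0 with a warning rather than left undefined.
    """
    true_labels = np.asarray(true_labels).astype(int)
    pred_labels = np.asarray(pred_labels).astype(int)
    if true_labels.shape != pred_labels.shape or true_labels.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    if not (np.isin(true_labels, (0, 1)).all() and np.isin(pred_labels, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    accuracy = float(np.mean(true_labels == pred_labels))
    tp = int(np.sum((true_labels == 1) & (pred_labels == 1)))
    fp = int(np.sum((true_labels == 0) & (pred_labels == 1)))
    fn = int(np.sum((true_labels == 1) & (pred_labels == 0)))
    if tp == 0:
        if fp == 0 and fn == 0:
            logger.warning("no positives in truth or prediction; F1 reported as 0")
        return accuracy, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return accuracy, float(2 * precision * recall / (precision + recall))


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (linear-interpolation quartiles)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median_iqr of empty input")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1)
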