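"""Model-comparison quantities: deviance, 0.5-cutoff classification, AUC,
Press's Q and a side-by-side model report.

For ungrouped binary data the saturated log-likelihood is zero, so the
residual deviance is simply ``-2 loglik``.  Classification uses a fixed
probability cutoff (default 0.5, boundary classified as 1).  Sensitivity and
specificity are recalls of the two true classes; which class anchors
"sensitivity" is an explicit argument (``sensitivity_class``), because
published tables for this model family report it for the majority
("developed", coded 0) class.  AUC is the rank-based (Mann-Whitney)
statistic with ties counted one half.  Press's Q,
``(N - n_correct * K)^2 / (N (K - 1))`` for K groups, is referred to
chi-square with 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitResult
from .model_core import predict_prob

__all__ = [
    "ClassificationReport",
    "deviance",
    "classify",
    "confusion_metrics",
    "auc",
    "press_q",
    "classification_report",
    "compare_models",
]


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts at a cutoff plus the derived summary metrics.

    ``confusion`` rows index the true class (0, 1) and columns the predicted
    class; proportions are on [0, 1] (multiply by 100 for the usual
    percentage presentation).
    """

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    press_q: float
    cutoff: float
    n: int
    sensitivity_class: int = 0


def deviance(fit: FitResult) -> float:
    """Residual deviance ``-2 loglik`` of a converged fit."""
    if not fit.converged:
        raise ValueError("deviance requires a converged fit")
    return -2.0 * fit.loglik


def classify(probs: np.ndarray, truth: np.ndarray,
             cutoff: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Threshold probabilities and tabulate the 2x2 confusion matrix.

    A probability exactly at the cutoff is classified as 1 (the boundary
    rule is fixed for determinism).  Returns ``(labels, confusion)`` with
    confusion rows = true class, columns = predicted class.
    """
    probs = np.asarray(probs, dtype=float).reshape(-1)
    truth = np.asarray(truth, dtype=float).reshape(-1)
    if probs.shape[0] != truth.shape[0]:
        raise ValueError("probs and truth must have equal length")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(truth, (0.0, 1.0))):
        raise ValueError("truth must be binary 0/1")
    labels = (probs >= cutoff).astype(int)
    confusion = np.zeros((2, 2), dtype=int)
    for t in (0, 1):
        for c in (0, 1):
            confusion[t, c] = int(np.sum((truth == t) & (labels == c)))
    return labels, confusion


def confusion_metrics(confusion: np.ndarray,
                      sensitivity_class: int = 0) -> dict[str, float]:
    """Accuracy and the two per-class recalls from a 2x2 table.

    ``sensitivity`` is the recall of ``sensitivity_class`` and
    ``specificity`` the recall of the other class.  An empty true class
    yields ``nan`` for its recall rather than 0.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2) or np.any(confusion < 0):
        raise ValueError("confusion must be a non-negative 2x2 table")
    n = int(confusion.sum())
    if n == 0:
        raise ValueError("confusion table is empty")
    if sensitivity_class not in (0, 1):
        raise ValueError("sensitivity_class must be 0 or 1")
    other = 1 - sensitivity_class
    accuracy = float(np.trace(confusion)) / n

    def _recall(cls: int) -> float:
        total = confusion[cls].sum()
        return float(confusion[cls, cls]) / total if total > 0 else float("nan")

    return {
        "accuracy": accuracy,
        "sensitivity": _recall(sensitivity_class),
        "specificity": _recall(other),
    }


def auc(truth: np.ndarray, probs: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, ties = 1/2."""
    truth = np.asarray(truth, dtype=float).reshape(-1)
    probs = np.asarray(probs, dtype=float).reshape(-1)
    if truth.shape[0] != probs.shape[0]:
        raise ValueError("truth and probs must have equal length")
    pos = truth == 1
    n1 = int(pos.sum())
    n0 = truth.shape[0] - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(probs)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def press_q(n_correct: int, n_total: int, n_groups: int = 2) -> float:
    """Press's Q statistic for classification beyond chance.

    ``Q = (N - n_correct * K)^2 / (N (K - 1))`` with N observations in K
    groups; Q is compared against chi-square with 1 df.
    """
    if n_total < 1 or not (0 <= n_correct <= n_total) or n_groups < 2:
        raise ValueError("need 0 <= n_correct <= n_total and n_groups >= 2")
    return float((n_total - n_correct * n_groups) ** 2
                 / (n_total * (n_groups - 1)))


def classification_report(truth: np.ndarray, probs: np.ndarray,
                          cutoff: float = 0.5,
                          sensitivity_class: int = 0) -> ClassificationReport:
    """Full in-sample classification summary at the given cutoff."""
    _, confusion = classify(probs, truth, cutoff)
    base = confusion_metrics(confusion, sensitivity_class)
    n = int(confusion.sum())
    n_correct = int(np.trace(confusion))
    return ClassificationReport(
        confusion=confusion,
        accuracy=base["accuracy"],
        sensitivity=base["sensitivity"],
        specificity=base["specificity"],
        auc=auc(truth, probs),
        press_q=press_q(n_correct, n, 2),
        cutoff=cutoff,
        n=n,
        sensitivity_class=sensitivity_class,
    )


def report_for_fit(fit: FitResult, cutoff: float = 0.5,
                   sensitivity_class: int = 0) -> ClassificationReport:
    """Convenience: in-sample classification report of a converged fit."""
    probs = predict_prob(fit.design, fit.theta_hat)
    return classification_report(fit.y, probs, cutoff, sensitivity_class)


def compare_models(entries: list[tuple[str, FitResult, ClassificationReport]]
                   ) -> pd.DataFrame:
    """Side-by-side deviance/AIC/classification table for >= 2 models.

    Flags the minimum-deviance and maximum-AUC rows; exact ties flag every
    tied row.
    """
    from .selection import aic as _aic

    if len(entries) < 2:
        raise ValueError("compare_models needs at least two models")
    n0 = entries[0][1].n
    y0 = entries[0][1].y
    for name, fit, _ in entries[1:]:
        if fit.n != n0 or not np.array_equal(fit.y, y0):
            raise ValueError(f"model {name!r} was fitted on different data")

    rows = []
    for name, fit, rep in entries:
        rows.append({
            "model": name,
            "deviance": deviance(fit),
            "aic": _aic(fit),
            "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "auc": rep.auc,
            "press_q": rep.press_q,
        })
    df = pd.DataFrame(rows).set_index("model")
    df["best_deviance"] = df["deviance"] == df["deviance"].min()
    df["best_auc"] = df["auc"] == df["auc"].max()
    return df
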