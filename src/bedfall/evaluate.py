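"""Evaluation: ranking metrics, F1-calibrated threshold, subgroup reports.

Threshold-free metrics (AUROC, AUPRC) rank the binary fall label c by the
predicted risk score; AUROC uses trapezoidal ROC integration (equivalently
the probability that a random positive outranks a random negative, ties
counting one half) and AUPRC uses step-wise average-precision integration,
which avoids the optimistic linear interpolation of the PR curve.

The decision threshold tau is calibrated once, on validation scores, by
maximizing F1 over all candidate thresholds — midpoints between
consecutive unique sorted scores plus -inf/+inf sentinels — with ties
broken toward the smaller tau (higher recall).  Predictions use the rule
``score >= tau``.  Precision with no predicted positives is 0 by
convention, as are recall and F1 with zero denominators.

Subgroup reports reuse the *globally* calibrated tau per posture mode; a
single-class subgroup gets NaN ranking metrics instead of an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


class UndefinedMetricError(ValueError):
    """Metric undefined for the given label composition."""


def _check_binary(labels: np.ndarray, need_both: bool = True, need_positive: bool = False):
    labels = np.asarray(labels)
    pos = int(np.sum(labels == 1))
    neg = int(np.sum(labels == 0))
    if pos + neg != len(labels):
        raise ValueError("labels must be binary 0/1")
    if need_both and (pos == 0 or neg == 0):
        raise UndefinedMetricError("both classes required")
    if need_positive and pos == 0:
        raise UndefinedMetricError("at least one positive required")
    return labels


def auroc(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """Area under the ROC curve of scores against binary labels."""
    labels = _check_binary(binary_labels)
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def auprc(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """Step-integrated area under the precision-recall curve."""
    labels = _check_binary(binary_labels, need_both=False, need_positive=True)
    return float(average_precision_score(labels, np.asarray(scores, float)))


def mse(predictions: np.ndarray, continuous_labels: np.ndarray) -> float:
    """Mean squared error against the continuous risk label."""
    predictions = np.asarray(predictions, float)
    continuous_labels = np.asarray(continuous_labels, float)
    if len(predictions) != len(continuous_labels):
        raise ValueError("length mismatch")
    if len(predictions) == 0:
        raise ValueError("empty input")
    return float(np.mean((predictions - continuous_labels) ** 2))


def thresholded_metrics(
    scores: np.ndarray, labels: np.ndarray, tau: float
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1) for the rule ``score >= tau``."""
    scores = np.asarray(scores, float)
    labels = _check_binary(labels, need_both=False)
    pred = scores >= tau
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    accuracy = (tp + tn) / len(labels)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return accuracy, precision, recall, f1


def calibrate_threshold(val_scores: np.ndarray, val_labels: np.ndarray) -> float:
    """F1-maximizing threshold over the midpoint candidate sweep.

    Candidates are the midpoints between consecutive unique sorted scores
    plus sentinels below the minimum and above the maximum; ties in F1 are
    broken toward the smaller threshold (higher recall).
    """
    scores = np.asarray(val_scores, float)
    labels = _check_binary(val_labels)
    uniq, inv = np.unique(scores, return_inverse=True)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    # positives/counts per unique score, then suffix sums: candidate i
    # predicts positive exactly the samples with score > uniq[i-1]
    pos_per = np.bincount(inv, weights=(labels == 1).astype(float), minlength=len(uniq))
    cnt_per = np.bincount(inv, minlength=len(uniq)).astype(float)
    tp = np.concatenate([[pos_per.sum()], pos_per.sum() - np.cumsum(pos_per)])
    npred = np.concatenate([[cnt_per.sum()], cnt_per.sum() - np.cumsum(cnt_per)])
    total_pos = pos_per.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(npred > 0, tp / np.maximum(npred, 1), 0.0)
        recall = tp / total_pos
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return float(candidates[int(np.argmax(f1))])  # argmax keeps the smaller tau on ties


@dataclass
class EvalReport:
    """Overall or per-posture metric bundle for one model/seed."""

    subgroup: str  # "overall" or a posture-mode name
    n_samples: int
    auroc: float
    auprc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    mse: float
    threshold: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate(
    scores: np.ndarray,
    binary_labels: np.ndarray,
    continuous_labels: np.ndarray,
    tau: float,
    subgroup: str = "overall",
) -> EvalReport:
    """All metrics for one score set at a fixed, pre-calibrated threshold."""
    labels = np.asarray(binary_labels, int)
    try:
        roc = auroc(scores, labels)
        pr = auprc(scores, labels)
    except UndefinedMetricError:
        roc = pr = float("nan")
    accuracy, precision, recall, f1 = thresholded_metrics(scores, labels, tau)
    return EvalReport(
        subgroup=subgroup,
        n_samples=len(labels),
        auroc=roc,
        auprc=pr,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        mse=mse(scores, continuous_labels),
        threshold=tau,
    )


def per_posture_report(
    scores: np.ndarray,
    binary_labels: np.ndarray,
    continuous_labels: np.ndarray,
    modes: np.ndarray,
    tau: float,
) -> list[EvalReport]:
    """Overall report plus one per posture mode, all at the same global tau."""
    scores = np.asarray(scores, float)
    modes = np.asarray(modes)
    reports = [evaluate(scores, binary_labels, continuous_labels, tau, "overall")]
    for mode in pd.unique(modes):
        sel = modes == mode
        reports.append(
            evaluate(
                scores[sel],
                np.asarray(binary_labels)[sel],
                np.asarray(continuous_labels)[sel],
                tau,
                str(mode),
            )
        )
    return reports


def aggregate_reports(reports: list[EvalReport]) -> pd.DataFrame:
    """Mean +- std rows over seeds, grouped by subgroup (long format)."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    metric_cols = ["auroc", "auprc", "accuracy", "precision", "recall", "f1", "mse"]
    agg = df.groupby("subgroup")[metric_cols].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
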