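"""Evaluation criteria for the fragment classifier.

Recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = their harmonic mean,
with transmissible as the positive class; fragments labelled uncertain
under a threshold t are excluded from these confusion counts.  The AUC is
always computed on all scores (thresholding does not alter ranks), by the
rank-based Mann–Whitney formulation with mid-rank tie handling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import PredictionRecord, UNCERTAIN, classify_score
from .simulator import TRANSMISSIBLE

__all__ = [
    "EvaluationReport",
    "confusion_metrics",
    "auc",
    "threshold_sweep",
    "sweep_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Metrics of one scored set at one uncertainty threshold."""

    group: str
    threshold_t: float
    recall: float
    precision: float
    f1: float
    auc: float
    uncertain_rate: float
    n_pos: int
    n_neg: int


def confusion_metrics(predictions: list[PredictionRecord],
                      truth: dict[str, str]) -> tuple[float, float, float]:
    """(recall, precision, f1) over certain predictions only.

    A zero denominator yields NaN for the affected metric, with a warning.
    """
    tp = fp = fn = tn = 0
    n_certain = 0
    for pred in predictions:
        if pred.label == UNCERTAIN:
            continue
        n_certain += 1
        true_pos = truth[pred.sequence_id] == TRANSMISSIBLE
        pred_pos = pred.label == TRANSMISSIBLE
        if pred_pos and true_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif true_pos:
            fn += 1
        else:
            tn += 1
    if n_certain == 0:
        raise ValueError("no certain predictions to evaluate")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator)", name)
            return math.nan
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    if recall and precision and not (math.isnan(recall) or math.isnan(precision)):
        f1 = 2 * recall * precision / (recall + precision)
    elif recall == 0 or precision == 0:
        f1 = 0.0
    else:
        f1 = math.nan
    return recall, precision, f1


def auc(scores: list[float], truth: list[int]) -> float:
    """Rank-based (Mann–Whitney) AUC with mid-rank ties.

    ``truth`` holds 1 for the positive (transmissible) class.  Equivalent to
    the probability that a random positive outranks a random negative, with
    ties counted half.
    """
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def threshold_sweep(predictions: list[PredictionRecord], truth: dict[str, str],
                    t_values: list[float], group: str = "") -> list[EvaluationReport]:
    """One report per uncertainty threshold on a fixed set of scored fragments.

    Each report relabels the fixed scores at its threshold; the uncertain
    rate is the fraction of all predictions labelled uncertain, and
    recall/precision/F1 are computed over the certain remainder.  The AUC
    is shared across thresholds.
    """
    scores = [p.score for p in predictions]
    y = [1 if truth[p.sequence_id] == TRANSMISSIBLE else 0 for p in predictions]
    shared_auc = auc(scores, y)
    n_pos, n_neg = sum(y), len(y) - sum(y)
    reports = []
    for t in t_values:
        relabelled = [
            PredictionRecord(p.sequence_id, p.score, p.window_scores,
                             classify_score(p.score, t), t)
            for p in predictions
        ]
        n_unc = sum(1 for p in relabelled if p.label == UNCERTAIN)
        if n_unc == len(relabelled):
            logger.warning("t=%.3g: every prediction uncertain; metrics undefined", t)
            recall = precision = f1 = math.nan
        else:
            recall, precision, f1 = confusion_metrics(relabelled, truth)
        reports.append(EvaluationReport(
            group=group, threshold_t=t, recall=recall, precision=precision,
            f1=f1, auc=shared_auc, uncertain_rate=n_unc / len(relabelled),
            n_pos=n_pos, n_neg=n_neg,
        ))
    return reports


def sweep_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
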