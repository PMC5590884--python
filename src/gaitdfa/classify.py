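"""Centroid distance-ratio classification and its evaluation.

A trial's DF-plane point is assigned to a condition by the ratio
r = d(point, shod centroid) / d(point, barefoot centroid): r < 1 -> shod,
r > 1 -> barefoot, r = 1 exactly -> unassigned (counted as an error). With
threshold 1 this is the nearest-centroid rule. Error rates are percentages
over all evaluated trials, with training-only and prediction-only breakdowns.
Shod is the positive class for the confusion matrix: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); a rate whose denominator is zero is reported as NaN,
never silently 0.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import NEGATIVE_CONDITION, POSITIVE_CONDITION
from .errors import DataError, ParameterError

UNASSIGNED = "unassigned"


def assign_by_centroid_ratio(
    df_points: np.ndarray,
    centroid_pos: np.ndarray,
    centroid_neg: np.ndarray,
    positive_label: str = POSITIVE_CONDITION,
    negative_label: str = NEGATIVE_CONDITION,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each DF-plane point by the distance ratio to the two centroids.

    Returns ``(labels, ratios)`` where ``ratios[i] = d(point_i, positive
    centroid) / d(point_i, negative centroid)``. A point sitting exactly on
    the positive centroid has ratio 0; a point equidistant from both has
    ratio 1 and is labelled ``"unassigned"``. The assignment outcome does not
    depend on which class sits in the numerator.
    """
    P = np.atleast_2d(np.asarray(df_points, dtype=float))
    c_pos = np.asarray(centroid_pos, dtype=float)
    c_neg = np.asarray(centroid_neg, dtype=float)
    if np.allclose(c_pos, c_neg):
        raise ParameterError("coincident centroids: distance ratio undefined")
    d_pos = np.linalg.norm(P - c_pos, axis=1)
    d_neg = np.linalg.norm(P - c_neg, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(d_neg > 0, d_pos / d_neg, np.inf)
    ratios = np.where((d_pos == 0) & (d_neg == 0), 1.0, ratios)
    labels = np.where(
        ratios < 1.0, positive_label, np.where(ratios > 1.0, negative_label, UNASSIGNED)
    )
    return labels, ratios


@dataclasses.dataclass
class ConfusionMatrix:
    """Trial counts with shod as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.P + self.N

    @property
    def sensitivity(self) -> float:
        """True positive rate TP/(TP+FN); NaN when no positive trials exist."""
        return self.TP / self.P if self.P else math.nan

    @property
    def specificity(self) -> float:
        """True negative rate TN/(TN+FP); NaN when no negative trials exist."""
        return self.TN / self.N if self.N else math.nan

    def as_dict(self) -> dict:
        return {"TP": self.TP, "FN": self.FN, "TN": self.TN, "FP": self.FP}


def _check_lengths(assigned, truth) -> tuple[np.ndarray, np.ndarray]:
    a, t = np.asarray(assigned), np.asarray(truth)
    if a.shape != t.shape:
        raise ParameterError(f"length mismatch: {a.shape} vs {t.shape}")
    return a, t


def error_rate(
    assigned: np.ndarray, truth: np.ndarray, is_training: np.ndarray | None = None
) -> dict:
    """Percentage of misassigned trials, overall and per partition.

    The overall rate covers ALL evaluated trials (training and predicted
    together); ``train_error_pct`` / ``test_error_pct`` are the same quantity
    restricted to each partition (NaN for an empty partition). Unassigned
    trials count as errors.
    """
    a, t = _check_lengths(assigned, truth)
    wrong = a != t

    def pct(mask: np.ndarray) -> float:
        return 100.0 * wrong[mask].mean() if mask.any() else math.nan

    full = np.ones(len(a), dtype=bool)
    out = {"overall_error_pct": pct(full)}
    if is_training is not None:
        tr = np.asarray(is_training, dtype=bool)
        if tr.shape != a.shape:
            raise ParameterError("partition flags length mismatch")
        out["train_error_pct"] = pct(tr)
        out["test_error_pct"] = pct(~tr)
    return out


def confusion_and_rates(
    assigned: np.ndarray,
    truth: np.ndarray,
    positive_label: str = POSITIVE_CONDITION,
    negative_label: str = NEGATIVE_CONDITION,
) -> ConfusionMatrix:
    """Build the confusion matrix; unassigned trials count against their true class."""
    a, t = _check_lengths(assigned, truth)
    known = {positive_label, negative_label}
    bad = set(t.tolist()) - known
    if bad:
        raise DataError(f"unknown truth label(s) {sorted(bad)}; expected {sorted(known)}")
    pos = t == positive_label
    correct = a == t
    return ConfusionMatrix(
        TP=int((pos & correct).sum()),
        FN=int((pos & ~correct).sum()),
        TN=int((~pos & correct).sum()),
        FP=int((~pos & ~correct).sum()),
    )


@dataclasses.dataclass
class EvalReport:
    """Full evaluation of one train/predict split.

    ``per_trial`` has one row per trial: subject, condition, partition, DF1,
    DF2, distance ratio, assigned label, correctness.
    """

    per_trial: pd.DataFrame
    overall_error_pct: float
    train_error_pct: float
    test_error_pct: float
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float

    def summary_dict(self) -> dict:
        return {
            "overall_error_pct": self.overall_error_pct,
            "train_error_pct": self.train_error_pct,
            "test_error_pct": self.test_error_pct,
            "confusion": self.confusion.as_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.per_trial.to_csv(path, index=False)


def evaluate_assignment(
    df_points: np.ndarray,
    truth: np.ndarray,
    subjects: np.ndarray,
    is_training: np.ndarray,
    centroid_pos: np.ndarray,
    centroid_neg: np.ndarray,
) -> EvalReport:
    """Assign every trial by the centroid-ratio rule and compile an EvalReport."""
    assigned, ratios = assign_by_centroid_ratio(df_points, centroid_pos, centroid_neg)
    rates = error_rate(assigned, truth, is_training)
    confusion = confusion_and_rates(assigned, truth)
    P = np.atleast_2d(df_points)
    per_trial = pd.DataFrame(
        {
            "subject_id": subjects,
            "condition": truth,
            "partition": np.where(np.asarray(is_training, bool), "training", "predicted"),
            "df1": P[:, 0],
            "df2": P[:, 1] if P.shape[1] > 1 else 0.0,
            "ratio": ratios,
            "assigned": assigned,
            "correct": assigned == truth,
        }
    )
    return EvalReport(
        per_trial=per_trial,
        overall_error_pct=rates["overall_error_pct"],
        train_error_pct=rates["train_error_pct"],
        test_error_pct=rates["test_error_pct"],
        confusion=confusion,
        sensitivity=confusion.sensitivity,
        specificity=confusion.specificity,
    )
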