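"""ROC curves, confusion-matrix statistics, and external validation reports."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EvaluationReport:
    """Confusion counts with the derived rates and (optional) ROC curve.

    All stored values are full precision; rounding to the presentation
    style (percents to 1 decimal, proportions to 3) happens only in
    :meth:`to_row`.  ``auc`` is None for class-label-only classifiers.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    auc: float | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")
        if self.n_total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def misclassification_rate(self) -> float:
        """Percent of subjects misclassified."""
        return 100.0 * (self.fp + self.fn) / self.n_total

    def to_row(self) -> dict:
        """Presentation-rounded row matching the report table layout."""
        return {
            "misclassification_rate_pct": round(self.misclassification_rate, 1),
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": round(self.sensitivity, 3)
            if not math.isnan(self.sensitivity) else math.nan,
            "specificity": round(self.specificity, 3)
            if not math.isnan(self.specificity) else math.nan,
            "auc": round(self.auc, 3) if self.auc is not None else None,
        }


def confusion_stats(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, misclassification %) from raw counts.

    Undefined rates (empty positive or negative truth) come back as NaN.
    """
    report = EvaluationReport(tp=tp, fp=fp, fn=fn, tn=tn)
    return report.sensitivity, report.specificity, report.misclassification_rate


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from continuous scores.

    Thresholds sweep the unique score values (ties grouped), so the
    trapezoidal area equals the rank-statistic AUC with ties counted 1/2.
    Returns (points, auc) where points is an (n, 2) array of (fpr, tpr)
    running from (0,0) to (1,1), monotone in both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # group ties: cumulative counts at the last index of each distinct score
    distinct_last = np.flatnonzero(np.diff(s, append=np.nan) != 0)
    cum_tp = np.cumsum(y)[distinct_last]
    cum_fp = np.cumsum(~y)[distinct_last]
    tpr = np.concatenate(([0.0], cum_tp / n_pos))
    fpr = np.concatenate(([0.0], cum_fp / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluation_report(labels, scores=None, predictions=None,
                      threshold: float = 0.5) -> EvaluationReport:
    """Build a report from truth labels plus scores and/or hard predictions.

    With ``scores`` given, predictions default to ``scores >= threshold``
    and the ROC/AUC is attached; with only ``predictions`` (class-vote
    classifiers), AUC is omitted.
    """
    labels = np.asarray(labels, dtype=bool)
    if scores is None and predictions is None:
        raise ValueError("provide scores and/or predictions")
    auc = None
    points = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        points, auc = roc_auc(scores, labels)
        if predictions is None:
            predictions = scores >= threshold
    predictions = np.asarray(predictions, dtype=bool)
    tp = int(np.sum(predictions & labels))
    fp = int(np.sum(predictions & ~labels))
    fn = int(np.sum(~predictions & labels))
    tn = int(np.sum(~predictions & ~labels))
    return EvaluationReport(tp=tp, fp=fp, fn=fn, tn=tn, auc=auc,
                            roc_points=points)


def validate_external(model, metrics_table: pd.DataFrame, labels,
                      training_ids=None, use_probabilities: bool = True,
                      ) -> EvaluationReport:
    """Apply a fitted model unchanged to a held-out cohort.

    Scoring is label-blind: the label column is consulted only after
    predictions exist.  Validation subject ids must be disjoint from
    ``training_ids`` when those are supplied.  For random forests the
    default output is majority-vote class labels (no AUC); probability
    mode is an explicitly labeled extension.
    """
    if training_ids is not None:
        overlap = set(metrics_table.index) & set(training_ids)
        if overlap:
            raise ValueError(
                f"validation subjects overlap training set: {sorted(overlap)[:5]}")
    rf_vote = model.method == "random_forest" and not use_probabilities
    if rf_vote:
        predictions = model.predict_class(metrics_table)
        scores = None
    else:
        scores = model.predict_proba(metrics_table)
        predictions = scores >= model.threshold
    return evaluation_report(np.asarray(labels, dtype=bool), scores=scores,
                             predictions=predictions, threshold=model.threshold)


def write_report_tsv(reports: dict[str, EvaluationReport], path) -> None:
    rows = []
    for name, rep in reports.items():
        row = {"model": name}
        row.update(rep.to_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_roc_csv(report: EvaluationReport, path) -> None:
    if report.roc_points is None:
        raise ValueError("report has no ROC points")
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        path, index=False)
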