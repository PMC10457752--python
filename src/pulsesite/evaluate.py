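"""Classification metrics for period-window site classification.

Two granularities are reported.  The per-period "probability" is the
fraction of individual cardiac-period windows classified correctly — a
continuity measure: a signal whose morphology is stable across beats
yields consistently classifiable periods.  The majority-vote accuracy
``Acc = Pred_correct / Pred_total`` classifies each whole signal by the
most frequent class among its period predictions and counts correct
signals.  Because fold composition varies across runs, reports are
aggregated as the elementwise median of the confusion matrices over
repeated runs (default 10), with metrics recomputed from the median
matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import ARTERY_CLASSES


@dataclass
class EvalReport:
    """Confusion matrix and derived metrics for one channel."""

    confusion: np.ndarray                  # (n_classes, n_classes) counts
    classes: tuple = ARTERY_CLASSES
    acc: float | None = None               # majority-vote signal accuracy
    avg_probability: float = 0.0           # trace / total of the matrix
    per_class_probability: dict = field(default_factory=dict)
    n_runs: int = 1
    channel: str | None = None

    @classmethod
    def from_confusion(cls, confusion: np.ndarray, classes=ARTERY_CLASSES,
                       acc: float | None = None, n_runs: int = 1,
                       channel: str | None = None) -> "EvalReport":
        probs = period_probability(confusion)
        return cls(confusion=np.asarray(confusion, dtype=float),
                   classes=tuple(classes), acc=acc,
                   avg_probability=probs["avg"],
                   per_class_probability={c: probs["per_class"][i]
                                          for i, c in enumerate(classes)},
                   n_runs=n_runs, channel=channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.classes),
                            columns=list(self.classes))


def confusion_from_predictions(y_true, y_pred,
                               classes=ARTERY_CLASSES) -> np.ndarray:
    """Count matrix: entry (i, j) = periods of true class i predicted as j."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    unknown = set(y_true) | set(y_pred)
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return m


def majority_vote(period_predictions, scores: np.ndarray | None = None):
    """Most frequent class among one signal's period predictions.

    Ties go to the class with the higher mean score, then to the lowest
    class index (alphabetical for the site labels).
    """
    preds = list(period_predictions)
    if not preds:
        raise ValueError("signal has no period predictions")
    counts = Counter(preds)
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1 or scores is None:
        return tied[0]
    preds_arr = np.asarray(preds)
    means = {c: float(np.mean([s for p, s in zip(preds_arr, scores) if p == c]))
             for c in tied}
    best = max(means.values())
    return sorted(c for c, v in means.items() if v == best)[0]


def signal_accuracy(per_signal_predictions: dict, per_signal_true: dict,
                    per_signal_scores: dict | None = None) -> float:
    """Majority-vote accuracy: correct signals / total signals."""
    if not per_signal_predictions:
        raise ValueError("no signals to score")
    correct = 0
    for sig, preds in per_signal_predictions.items():
        scores = per_signal_scores.get(sig) if per_signal_scores else None
        if majority_vote(preds, scores) == per_signal_true[sig]:
            correct += 1
    return correct / len(per_signal_predictions)


def period_probability(confusion: np.ndarray) -> dict:
    """Per-class and average fraction of correctly classified periods."""
    m = np.asarray(confusion, dtype=float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row_sums = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0, np.diag(m) / row_sums, np.nan)
    return {"avg": float(np.trace(m) / total), "per_class": per_class}


def median_over_runs(reports: list[EvalReport],
                     of_metrics: bool = False) -> EvalReport:
    """Elementwise median of the run confusion matrices.

    Metrics are recomputed from the median matrix (default); with
    ``of_metrics=True`` the metrics themselves are medianed instead and
    the median matrix is reported alongside.
    """
    if not reports:
        raise ValueError("need at least one run report")
    shapes = {r.confusion.shape for r in reports}
    if len(shapes) != 1:
        raise ValueError("run reports have mismatched confusion shapes")
    med = np.median(np.stack([r.confusion for r in reports]), axis=0)
    accs = [r.acc for r in reports if r.acc is not None]
    out = EvalReport.from_confusion(
        med, classes=reports[0].classes,
        acc=float(np.median(accs)) if accs else None,
        n_runs=len(reports), channel=reports[0].channel)
    if of_metrics:
        out.avg_probability = float(np.median(
            [r.avg_probability for r in reports]))
        out.per_class_probability = {
            c: float(np.median([r.per_class_probability[c] for r in reports]))
            for c in reports[0].classes}
    return out


def frequency_sweep_table(reports_by_channel: dict[str, EvalReport]
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary tables across channels.

    Returns (overall, per_site): one row per channel with average accuracy
    and average per-period probability, and a per-site probability table
    with one row per acquisition site and one column per channel.
    """
    overall = pd.DataFrame(
        [{"signal": ch, "avg_acc": r.acc, "avg_prob": r.avg_probability}
         for ch, r in reports_by_channel.items()])
    per_site = pd.DataFrame(
        {ch: pd.Series(r.per_class_probability)
         for ch, r in reports_by_channel.items()})
    per_site.index.name = "site"
    return overall, per_site
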