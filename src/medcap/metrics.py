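"""Slot-wise evaluation: token accuracy, F1, unigram-precision BLEU-1, and
one-vs-rest confusion-matrix metric tables.

A generated caption here is an ordered three-word description
(exam type, body part, identified problem). Each of the three slots is
scored as an ordinary multiclass classification problem: a square confusion
matrix with true classes on the rows and predicted classes on the columns,
reduced per class to the 2x2 quantities P, N, TP, FP, TN, FN and the rates
TPR, TNR, PPV, NPV, ACC, F1.

Rates whose denominator is empty are UNDEFINED and rendered as "-" in
tables; in particular PPV is undefined only when the class is never
predicted (TP+FP=0), and F1 is undefined whenever TP=0 (the harmonic mean
of precision and sensitivity has an empty or zero denominator there).
Rates are rounded half-up to two decimals for table output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "UNDEFINED",
    "SLOTS",
    "SlotConfusion",
    "MetricRow",
    "token_accuracy",
    "f1_score",
    "bleu1",
    "build_slot_confusion",
    "confusion_metrics",
    "metric_table",
    "round2",
    "PAD_TOKEN",
]

#: sentinel for rates with an empty denominator (printed as "-")
UNDEFINED = None

SLOTS = ("exam_type", "body_part", "problem")
_SLOT_INDEX = {s: i for i, s in enumerate(SLOTS)}

PAD_TOKEN = "<pad>"


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, the convention of the metric tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SlotConfusion:
    """Square confusion matrix: rows = true class, columns = predicted class."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValidationError("labels/counts size mismatch")
        if (counts < 0).any():
            raise ValidationError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricRow:
    """The 12 per-class quantities of a one-vs-rest metric table."""

    class_label: str
    P: int
    N: int
    TP: int
    FP: int
    TN: int
    FN: int
    TPR: float | None
    TNR: float | None
    PPV: float | None
    NPV: float | None
    ACC: float | None
    F1: float | None

    def formatted(self) -> dict:
        """Counts as ints, rates as 2-decimal strings, UNDEFINED as '-'."""
        out = {"Class": self.class_label}
        for f in ("P", "N", "TP", "FP", "TN", "FN"):
            out[f] = int(getattr(self, f))
        for f in ("TPR", "TNR", "PPV", "NPV", "ACC", "F1"):
            v = getattr(self, f)
            out[f] = "-" if v is UNDEFINED else f"{round2(v):.2f}"
        return out


def token_accuracy(predictions, references) -> float:
    """Fraction of correctly generated words over all generated positions.

    Each prediction is compared position by position against its reference
    (the prediction is implicitly padded to the reference length); padding
    tokens in the reference are not scored.
    """
    if len(predictions) == 0 or len(predictions) != len(references):
        raise ValidationError("predictions and references must be aligned and non-empty")
    correct = total = 0
    for pred, ref in zip(predictions, references):
        for i, r in enumerate(ref):
            if r == PAD_TOKEN:
                continue
            total += 1
            if i < len(pred) and pred[i] == r:
                correct += 1
    if total == 0:
        raise ValidationError("no scorable (non-padding) reference tokens")
    return correct / total


def f1_score(precision, sensitivity):
    """Harmonic mean of precision and sensitivity; UNDEFINED when degenerate."""
    if precision is UNDEFINED or sensitivity is UNDEFINED:
        return UNDEFINED
    if precision + sensitivity == 0:
        return UNDEFINED
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def bleu1(predictions, references) -> float:
    """Corpus-level unigram precision.

    Per caption pair, each predicted unigram counts as correct up to the
    number of times it occurs in the reference (count clipping); the
    corpus score is total clipped matches over total predicted unigrams.
    No brevity penalty is applied.
    """
    if len(predictions) == 0 or len(predictions) != len(references):
        raise ValidationError("predictions and references must be aligned and non-empty")
    matched = predicted = 0
    for pred, ref in zip(predictions, references):
        pc, rc = Counter(pred), Counter(ref)
        predicted += sum(pc.values())
        matched += sum(min(c, rc[w]) for w, c in pc.items())
    if predicted == 0:
        raise ValidationError("zero predicted unigrams")
    return matched / predicted


def build_slot_confusion(predicted_triples, true_triples, slot: str) -> SlotConfusion:
    """Confusion matrix for one slot of aligned caption triples.

    Class order: descending true-class frequency, ties (and never-true
    predicted classes) lexicographic.
    """
    if slot not in _SLOT_INDEX:
        raise ValidationError(f"unknown slot {slot!r}")
    if len(predicted_triples) != len(true_triples):
        raise ValidationError("predicted and true triples must be aligned")
    k = _SLOT_INDEX[slot]
    truths = [t[k] for t in true_triples]
    preds = [p[k] for p in predicted_triples]
    freq = Counter(truths)
    labels = sorted(set(truths) | set(preds), key=lambda w: (-freq[w], w))
    idx = {w: i for i, w in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truths, preds):
        counts[idx[t], idx[p]] += 1
    return SlotConfusion(tuple(labels), counts)


def confusion_metrics(matrix: SlotConfusion) -> list[MetricRow]:
    """One-vs-rest reduction of a multiclass confusion matrix.

    For each class: TP is the diagonal cell, FN the rest of its row, FP the
    rest of its column, TN everything else; TPR=TP/P, TNR=TN/N,
    PPV=TP/(TP+FP), NPV=TN/(TN+FN), ACC=(TP+TN)/total, F1 the harmonic mean
    of PPV and TPR. Rates keep full precision here; ``MetricRow.formatted``
    applies the 2-decimal table convention.
    """
    c = matrix.counts
    total = matrix.grand_total
    rows = []
    for i, label in enumerate(matrix.labels):
        tp = int(c[i, i])
        fn = int(c[i, :].sum()) - tp
        fp = int(c[:, i].sum()) - tp
        tn = total - tp - fn - fp
        p, n = tp + fn, fp + tn
        tpr = tp / p if p else UNDEFINED
        tnr = tn / n if n else UNDEFINED
        ppv = tp / (tp + fp) if tp + fp else UNDEFINED
        npv = tn / (tn + fn) if tn + fn else UNDEFINED
        acc = (tp + tn) / total if total else UNDEFINED
        rows.append(
            MetricRow(label, p, n, tp, fp, tn, fn, tpr, tnr, ppv, npv, acc, f1_score(ppv, tpr))
        )
    return rows


def metric_table(matrix: SlotConfusion) -> pd.DataFrame:
    """Render the metric table with the printed header and dash convention."""
    return pd.DataFrame([r.formatted() for r in confusion_metrics(matrix)])
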