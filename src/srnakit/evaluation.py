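"""Four-class benchmark scoring of pipeline predictions against ground truth.

Reads fall into four classes: known miRNA, novel miRNA, known piRNA, and
"other" (the rejection class, which in simulated data holds the altered
decoy reads).  The confusion cells follow the benchmark convention for
this setting:

* TP — a read correctly assigned to its true class (classes 1-3);
* FP — a read assigned to class *x* (1-3) that belongs to a different class;
* FN — a read of a true class 1-3 rejected to class 4;
* TN — a true class-4 (decoy) read also labelled class 4.

Every scored read contributes to exactly one overall cell, so
``TP + FP + FN + TN`` equals the number of scored reads.  A read predicted
as the wrong non-rejection class counts as FP to the predicted class (not
additionally as FN — FN is reserved for rejection).

Metrics: accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
recall = TP/(TP+FN); F1 = 2PR/(P+R); all reported as percentages.
Report-style percentages (%FP, %FN, concordance) are truncated — not
rounded — to two decimals, matching how such tables are usually printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .reference_io import RnaClass

POSITIVE_CLASSES = (
    RnaClass.KNOWN_MIRNA,
    RnaClass.NOVEL_MIRNA,
    RnaClass.KNOWN_PIRNA,
)


@dataclass
class ConfusionSummary:
    """Overall and per-class TP/FP/FN/TN tallies (read-weighted)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    per_class: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_class(value: str | RnaClass) -> RnaClass:
    return value if isinstance(value, RnaClass) else RnaClass(value)


def score_against_truth(
    predictions: Mapping[str, str | RnaClass],
    truth: Mapping[str, str | RnaClass],
    weights: Mapping[str, int] | None = None,
) -> ConfusionSummary:
    """Tally confusion cells for predictions keyed by read/molecule id.

    ``weights`` (e.g. per-molecule expression counts) multiply each id's
    contribution; default weight is 1.  A truth id with no prediction is
    treated as rejected to class 4.  A prediction id absent from truth is
    an error.
    """
    for pid in predictions:
        if pid not in truth:
            raise KeyError(f"prediction id {pid!r} not present in ground truth")
    cs = ConfusionSummary(
        per_class={
            c.value: {"tp": 0, "fp": 0, "fn": 0, "tn": 0} for c in POSITIVE_CLASSES
        }
    )
    for tid, true_raw in truth.items():
        true_class = _as_class(true_raw)
        pred_class = _as_class(predictions.get(tid, RnaClass.OTHER))
        w = int(weights[tid]) if weights is not None else 1
        if pred_class is not RnaClass.OTHER:
            if pred_class is true_class:
                cs.tp += w
                cs.per_class[pred_class.value]["tp"] += w
            else:
                cs.fp += w
                cs.per_class[pred_class.value]["fp"] += w
        else:
            if true_class is RnaClass.OTHER:
                cs.tn += w
                for cell in cs.per_class.values():
                    cell["tn"] += w
            else:
                cs.fn += w
                cs.per_class[true_class.value]["fn"] += w
    return cs


def accuracy(cs: ConfusionSummary) -> float:
    """(TP+TN)/(TP+TN+FP+FN) as a percentage."""
    if cs.total == 0:
        raise ValueError("cannot compute accuracy of an empty summary")
    return 100.0 * (cs.tp + cs.tn) / cs.total


def precision(cs: ConfusionSummary) -> float:
    """TP/(TP+FP) as a percentage (0 when TP+FP = 0)."""
    denom = cs.tp + cs.fp
    return 100.0 * cs.tp / denom if denom else 0.0


def recall(cs: ConfusionSummary) -> float:
    """TP/(TP+FN) as a percentage (0 when TP+FN = 0)."""
    denom = cs.tp + cs.fn
    return 100.0 * cs.tp / denom if denom else 0.0


def f1(cs: ConfusionSummary) -> float:
    """Harmonic mean of precision and recall, as a percentage.

    By convention F1 = 0 when precision + recall = 0.
    """
    p = precision(cs)
    r = recall(cs)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def truncate2(value: float) -> float:
    """Truncate (floor) a non-negative percentage to two decimals."""
    return math.floor(value * 100) / 100


def pct_false_positive(n_identified: int, n_validated: int) -> float:
    """Share of pipeline-identified molecules that failed external validation.

    ``(1 - n_validated / n_identified) * 100``, truncated to two decimals.
    """
    if n_identified <= 0:
        raise ValueError("n_identified must be positive")
    if not 0 <= n_validated <= n_identified:
        raise ValueError("n_validated must lie in [0, n_identified]")
    return truncate2((1 - n_validated / n_identified) * 100)


def pct_false_negative(n_validated_found: int, n_total_validated: int) -> float:
    """Share of externally validated molecules the pipeline missed.

    ``(1 - n_validated_found / n_total_validated) * 100``, truncated to two
    decimals.
    """
    if n_total_validated <= 0:
        raise ValueError("n_total_validated must be positive")
    if not 0 <= n_validated_found <= n_total_validated:
        raise ValueError("n_validated_found must lie in [0, n_total_validated]")
    return truncate2((1 - n_validated_found / n_total_validated) * 100)


def pct_concordance(n_matched: int, n_total: int) -> float:
    """Literature-concordance ratio ``100 * n_matched / n_total``, truncated
    to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_matched <= n_total:
        raise ValueError("n_matched must lie in [0, n_total]")
    return truncate2(100.0 * n_matched / n_total)


def pirna_share(n_pirna_reads: int, n_mirna_reads: int) -> float:
    """Percentage of annotated small-RNA reads that are piRNAs:
    ``100 * pi / (pi + mi)``."""
    if n_pirna_reads < 0 or n_mirna_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = n_pirna_reads + n_mirna_reads
    if total == 0:
        raise ValueError("no annotated reads")
    return 100.0 * n_pirna_reads / total


def metric_report(cs: ConfusionSummary) -> dict:
    """Overall and per-class metrics as a JSON-serialisable dict."""
    report: dict = {
        "cells": {"TP": cs.tp, "FP": cs.fp, "FN": cs.fn, "TN": cs.tn},
        "accuracy": accuracy(cs),
        "precision": precision(cs),
        "recall": recall(cs),
        "f1": f1(cs),
        "per_class": {},
    }
    for cls, cells in cs.per_class.items():
        sub = ConfusionSummary(
            tp=cells["tp"], fp=cells["fp"], fn=cells["fn"], tn=cells["tn"]
        )
        report["per_class"][cls] = {
            "cells": {"TP": sub.tp, "FP": sub.fp, "FN": sub.fn, "TN": sub.tn},
            "accuracy": accuracy(sub) if sub.total else float("nan"),
            "precision": precision(sub),
            "recall": recall(sub),
            "f1": f1(sub),
        }
    return report
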