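"""Diagnostic-accuracy metrics and discrepancy review.

Predictions are compared against manually abstracted gold labels exactly
as a validation study would: per attribute, a 2x2 confusion matrix yields
sensitivity, specificity, positive and negative predictive value and
overall accuracy, all as percentages; categorical attributes (ASPECTS
band, collateral status) are evaluated one-vs-rest per class plus a
single exact-match overall accuracy. A metric whose denominator is zero
(e.g. no gold positives for a rare finding in a small cohort) is reported
as undefined and rendered "NA", never silently coerced to 0 or 100.

The discrepancy report lists every (report, attribute) gold/prediction
mismatch together with the rule matches that produced the prediction, so
a reviewer can see exactly which pattern fired — the raw material for
iterative rule refinement.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .rule_engine import Prediction
from .schema import AttributeSchema, Report, STROKE_SCHEMA

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "DiscrepancyRecord",
    "confusion",
    "binary_metrics",
    "categorical_metrics",
    "prevalence",
    "percent_agreement",
    "discrepancy_report",
    "split_corpus",
    "evaluate_predictions",
    "metrics_to_frame",
    "write_metrics_csv",
    "write_discrepancies",
    "round1",
]


class PairingError(ValueError):
    """Gold and predicted sequences cannot be aligned."""


class EmptyEvaluationError(ValueError):
    """No reports to evaluate."""


def round1(x: Optional[float]) -> Optional[float]:
    """Round to 1 decimal, half away from zero (presentation only)."""
    if x is None:
        return None
    q = Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    gold: Sequence[str], pred: Sequence[str], positive_class: str
) -> ConfusionMatrix:
    """Standard 2x2 counts treating ``positive_class`` as positive."""
    if len(gold) != len(pred):
        raise PairingError(
            f"gold ({len(gold)}) and pred ({len(pred)}) differ in length"
        )
    tp = fp = tn = fn = 0
    for g, p in zip(gold, pred):
        g_pos = g == positive_class
        p_pos = p == positive_class
        if g_pos and p_pos:
            tp += 1
        elif g_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


@dataclass
class ClassMetrics:
    """Metrics of one (attribute, positive class) pair, unrounded.

    ``None`` marks an undefined metric (zero denominator).
    """

    class_label: str
    cm: ConfusionMatrix
    prevalence_n: int
    prevalence_pct: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float


@dataclass
class MetricsReport:
    """Per-attribute validation report (one row per positive class)."""

    attribute: str
    kind: str
    rows: list[ClassMetrics]
    overall_accuracy: float


def _class_metrics(class_label: str, cm: ConfusionMatrix) -> ClassMetrics:
    if cm.n == 0:
        raise EmptyEvaluationError("cannot compute metrics on 0 reports")
    return ClassMetrics(
        class_label=class_label,
        cm=cm,
        prevalence_n=cm.tp + cm.fn,
        prevalence_pct=100.0 * (cm.tp + cm.fn) / cm.n,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=100.0 * (cm.tp + cm.tn) / cm.n,
    )


def binary_metrics(
    cm: ConfusionMatrix, attribute: str = "", class_label: str = "present"
) -> MetricsReport:
    """Sensitivity/specificity/PPV/NPV/accuracy from one 2x2 matrix.

    Values are kept unrounded internally; rounding to one decimal happens
    only at presentation (:func:`round1`). Zero denominators yield the
    undefined marker ``None`` rather than raising.
    """
    row = _class_metrics(class_label, cm)
    return MetricsReport(
        attribute=attribute,
        kind="binary",
        rows=[row],
        overall_accuracy=row.accuracy,
    )


def categorical_metrics(
    gold: Sequence[str],
    pred: Sequence[str],
    attr: AttributeSchema,
) -> MetricsReport:
    """One-vs-rest metrics per class plus exact-match overall accuracy."""
    if len(gold) != len(pred):
        raise PairingError(
            f"gold ({len(gold)}) and pred ({len(pred)}) differ in length"
        )
    if not gold:
        raise EmptyEvaluationError("cannot compute metrics on 0 reports")
    for value in list(gold) + list(pred):
        if value not in attr.classes:
            raise ValueError(f"{attr.name}: unknown class {value!r}")
    rows = [
        _class_metrics(c, confusion(gold, pred, c)) for c in attr.classes
    ]
    exact = sum(g == p for g, p in zip(gold, pred))
    return MetricsReport(
        attribute=attr.name,
        kind="categorical",
        rows=rows,
        overall_accuracy=100.0 * exact / len(gold),
    )


def prevalence(
    labels: Sequence[str], positive_class: str
) -> tuple[int, float]:
    """Count of the positive class and its percentage (1-decimal)."""
    if not labels:
        raise EmptyEvaluationError("prevalence of an empty label list")
    count = sum(label == positive_class for label in labels)
    return count, round1(100.0 * count / len(labels))


def percent_agreement(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> float:
    """Raw inter-rater agreement: percent of positions with equal class."""
    if len(labels_a) != len(labels_b):
        raise PairingError("label lists differ in length")
    if not labels_a:
        raise EmptyEvaluationError("agreement of empty label lists")
    equal = sum(a == b for a, b in zip(labels_a, labels_b))
    return 100.0 * equal / len(labels_a)


@dataclass
class DiscrepancyRecord:
    """One gold/prediction mismatch surfaced for human review."""

    report_id: str
    attribute: str
    gold: str
    predicted: str
    trace: list[dict] = field(default_factory=list)
    resolution: str = "unresolved"

    def to_json_obj(self) -> dict:
        return {
            "report_id": self.report_id,
            "attribute": self.attribute,
            "gold": self.gold,
            "predicted": self.predicted,
            "trace": self.trace,
            "resolution": self.resolution,
        }


def discrepancy_report(
    reports: Sequence[Report],
    predictions: Sequence[Prediction],
) -> list[DiscrepancyRecord]:
    """One record per (report, attribute) gold-vs-predicted mismatch.

    Each record carries the matched-rule trace for its attribute so the
    reviewer can see which pattern fired. Reports must have gold labels
    and align one-to-one with the predictions by id.
    """
    if len(reports) != len(predictions):
        raise PairingError("reports and predictions differ in length")
    records: list[DiscrepancyRecord] = []
    for report, pred in zip(reports, predictions):
        if report.id != pred.report_id:
            raise PairingError(
                f"id mismatch: report {report.id!r} vs prediction "
                f"{pred.report_id!r}"
            )
        if report.labels is None:
            raise ValueError(f"report {report.id!r} has no gold labels")
        for attribute, gold_class in report.labels.items():
            predicted = pred.classes[attribute]
            if predicted == gold_class:
                continue
            bundle = pred.bundles.get(attribute)
            trace = []
            if bundle is not None:
                trace = [
                    {
                        "rule_id": m.rule_id,
                        "sentence_index": m.sentence_index,
                        "span": list(m.span),
                    }
                    for m in bundle.matches
                ]
            records.append(
                DiscrepancyRecord(
                    report_id=report.id,
                    attribute=attribute,
                    gold=gold_class,
                    predicted=predicted,
                    trace=trace,
                )
            )
    return records


def split_corpus(
    corpus: Sequence[Report], train_fraction: float, seed: int
) -> tuple[list[Report], list[Report]]:
    """Seeded random partition into (train, validation).

    ``|train| = round(train_fraction * n)`` (half away from zero); the two
    cohorts are disjoint, exhaustive, keep the original corpus order, and
    are deterministic given the seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(corpus)
    k = int(math.floor(train_fraction * n + 0.5))
    rng = random.Random(seed)
    indices = list(range(n))
    rng.shuffle(indices)
    train_idx = set(indices[:k])
    train = [r for i, r in enumerate(corpus) if i in train_idx]
    valid = [r for i, r in enumerate(corpus) if i not in train_idx]
    return train, valid


def evaluate_predictions(
    reports: Sequence[Report],
    predictions: Sequence[Prediction],
    schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
) -> dict[str, MetricsReport]:
    """Full per-attribute metrics for a labeled corpus."""
    if not reports:
        raise EmptyEvaluationError("no reports to evaluate")
    if any(r.labels is None for r in reports):
        raise ValueError("every report needs gold labels for evaluation")
    out: dict[str, MetricsReport] = {}
    for name, attr in schema.items():
        gold = [r.labels[name] for r in reports]
        pred = [p.classes[name] for p in predictions]
        if attr.is_binary:
            out[name] = binary_metrics(
                confusion(gold, pred, "present"), attribute=name
            )
        else:
            out[name] = categorical_metrics(gold, pred, attr)
    return out


def metrics_to_frame(
    metrics: Mapping[str, MetricsReport], cohort: str = "all"
) -> pd.DataFrame:
    """Flatten metrics into the tabular report layout.

    One row per (attribute, class); categorical attributes get an extra
    ``overall`` row carrying only the exact-match accuracy. Percentages
    are rounded to one decimal; undefined cells render "NA".
    """

    def cell(x: Optional[float]):
        return "NA" if x is None else round1(x)

    rows = []
    for name, report in metrics.items():
        for cm_row in report.rows:
            rows.append(
                {
                    "cohort": cohort,
                    "attribute": name,
                    "class": cm_row.class_label,
                    "prevalence_n": cm_row.prevalence_n,
                    "prevalence_pct": round1(cm_row.prevalence_pct),
                    "sensitivity": cell(cm_row.sensitivity),
                    "specificity": cell(cm_row.specificity),
                    "ppv": cell(cm_row.ppv),
                    "npv": cell(cm_row.npv),
                    "accuracy": round1(cm_row.accuracy),
                }
            )
        if report.kind == "categorical":
            rows.append(
                {
                    "cohort": cohort,
                    "attribute": name,
                    "class": "overall",
                    "prevalence_n": None,
                    "prevalence_pct": None,
                    "sensitivity": None,
                    "specificity": None,
                    "ppv": None,
                    "npv": None,
                    "accuracy": round1(report.overall_accuracy),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cohort", "attribute", "class", "prevalence_n", "prevalence_pct",
            "sensitivity", "specificity", "ppv", "npv", "accuracy",
        ],
    )


def write_metrics_csv(
    metrics_by_cohort: Mapping[str, Mapping[str, MetricsReport]],
    path: str | Path,
) -> None:
    """Write the metrics table for one or more cohorts as CSV."""
    frames = [
        metrics_to_frame(metrics, cohort)
        for cohort, metrics in metrics_by_cohort.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_discrepancies(
    records: Iterable[DiscrepancyRecord], path: str | Path
) -> None:
    """Write discrepancy records as JSON-lines."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record.to_json_obj(), ensure_ascii=False))
            fh.write("\n")
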