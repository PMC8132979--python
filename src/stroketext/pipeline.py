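"""File-level workflow: simulate → split → extract → evaluate → review.

These functions wire the stages together around the on-disk formats
(JSON-lines corpora and predictions, CSV metrics, JSON-lines
discrepancies) so a whole validation study can be replayed from a few
calls — see the ``examples/`` scripts for the narrative versions. The
train/validation split is materialised as id-list files so cohort
membership stays auditable. Everything is deterministic given the seeds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

from .evaluation import (
    MetricsReport,
    discrepancy_report,
    evaluate_predictions,
    prevalence,
    split_corpus,
    write_discrepancies,
    write_metrics_csv,
)
from .rule_engine import (
    Prediction,
    RuleSet,
    compile_ruleset,
    predict_corpus,
    write_predictions,
)
from .schema import Report, STROKE_SCHEMA, read_corpus, write_corpus
from .stroke_rules import load_default_rules
from .synthetic_data import SimConfig, generate_corpus

__all__ = [
    "simulate_to_file",
    "split_to_files",
    "extract_to_file",
    "evaluate_to_files",
    "prevalence_summary",
]


def prevalence_summary(reports: Sequence[Report]) -> dict[str, tuple[int, float]]:
    """Per-attribute (count, percent) of reports with a non-default label.

    For binary findings this is the prevalence of ``present``; for the
    gradings it is the share of reports where the attribute is reported
    at all.
    """
    out: dict[str, tuple[int, float]] = {}
    for name, attr in STROKE_SCHEMA.items():
        labels = [r.labels[name] for r in reports if r.labels is not None]
        flags = [
            "pos" if label != attr.default_class else "neg" for label in labels
        ]
        out[name] = prevalence(flags, "pos")
    return out


def simulate_to_file(config: SimConfig, corpus_path: str | Path) -> list[Report]:
    """Generate a synthetic corpus and write it as JSON-lines."""
    corpus = generate_corpus(config)
    write_corpus(corpus, corpus_path)
    return corpus


def split_to_files(
    corpus_path: str | Path,
    train_fraction: float,
    seed: int,
    train_ids_path: str | Path,
    valid_ids_path: str | Path,
) -> tuple[list[Report], list[Report]]:
    """Split a corpus and materialise cohort membership as id lists."""
    corpus = read_corpus(corpus_path)
    train, valid = split_corpus(corpus, train_fraction, seed)
    for cohort, path in ((train, train_ids_path), (valid, valid_ids_path)):
        Path(path).write_text(
            "".join(f"{r.id}\n" for r in cohort), encoding="utf-8"
        )
    return train, valid


def extract_to_file(
    corpus_path: str | Path,
    predictions_path: str | Path,
    rules: Optional[RuleSet | str | Path] = None,
) -> list[Prediction]:
    """Run the rule engine over a corpus file, one prediction per record.

    ``rules`` may be a compiled :class:`RuleSet`, a path to a JSON rule
    file, or None for the shipped default library. Input order is
    preserved.
    """
    if rules is None:
        ruleset = load_default_rules()
    elif isinstance(rules, RuleSet):
        ruleset = rules
    else:
        ruleset = compile_ruleset(rules)
    corpus = read_corpus(corpus_path)
    predictions = predict_corpus(corpus, ruleset)
    write_predictions(predictions, predictions_path)
    return predictions


def evaluate_to_files(
    cohorts: Mapping[str, tuple[Sequence[Report], Sequence[Prediction]]],
    metrics_csv_path: str | Path,
    discrepancies_path: Optional[str | Path] = None,
) -> dict[str, dict[str, MetricsReport]]:
    """Evaluate one or more labeled cohorts and write the report files.

    ``cohorts`` maps a cohort name (e.g. ``train`` / ``validation``) to
    its (gold reports, predictions) pair. Writes the combined metrics CSV
    and, if requested, the discrepancy JSON-lines across all cohorts.
    """
    metrics_by_cohort: dict[str, dict[str, MetricsReport]] = {}
    all_records = []
    for cohort, (reports, predictions) in cohorts.items():
        metrics_by_cohort[cohort] = evaluate_predictions(reports, predictions)
        all_records.extend(discrepancy_report(reports, predictions))
    write_metrics_csv(metrics_by_cohort, metrics_csv_path)
    if discrepancies_path is not None:
        write_discrepancies(all_records, discrepancies_path)
    return metrics_by_cohort
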