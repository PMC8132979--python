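"""Weighted sentence-level regular-expression rule engine.

Each rule is a regular expression applied to one sentence at a time and
carries a signed weight toward one class of one attribute: a positive
weight raises the evidence for that class, a negative weight (a negation
or exclusion rule such as "no evidence of ...") lowers it. Per attribute,
the signed weights of all matched rules are summed into per-class scores;
for binary attributes the score of ``present`` is mapped through the
standard logistic to a probability, and the report is classified
``present`` iff the score is strictly positive. A rule matches at most
once per sentence, so repeated phrases cannot inflate the score, and a
rule can never combine evidence across two sentences — the engine has no
knowledge of vascular anatomy beyond what a single sentence states, which
is both its mechanism and its documented failure mode.

The ASPECTS grading is extracted separately: a mention pattern must
produce an integer 0–10, the first valid mention in document order wins,
and the value is banded as ``lt5`` / ``ge5``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .preprocess import DEFAULT_ABBREVIATIONS, Sentence, segment_sentences
from .schema import (
    ABSENT,
    NOT_REPORTED,
    PRESENT,
    AttributeSchema,
    Report,
    SchemaError,
    STROKE_SCHEMA,
)

__all__ = [
    "Rule",
    "RuleSet",
    "Match",
    "ScoreBundle",
    "Prediction",
    "RuleCompilationError",
    "compile_ruleset",
    "match_rules",
    "score_attribute",
    "classify",
    "extract_aspects",
    "predict_report",
    "predict_corpus",
    "write_predictions",
    "read_predictions",
    "ASPECTS_TOKEN_PATTERN",
    "ASPECT_SCORE_PATTERN",
]


class RuleCompilationError(ValueError):
    """A rule definition failed to compile; the message names the rule_id."""


@dataclass(frozen=True)
class Rule:
    """One sentence-scoped pattern with a signed weight.

    ``weight`` must be non-zero: its sign is the evidential direction
    (raise vs lower the target class). Matching is case-insensitive unless
    ``case_sensitive`` — the opt-in exists for the ASPECT/aspect homonym.
    """

    rule_id: str
    attribute: str
    target_class: str
    pattern: str
    weight: float
    case_sensitive: bool = False
    note: str = ""


@dataclass(frozen=True)
class _CompiledRule:
    rule: Rule
    regex: re.Pattern


@dataclass(frozen=True)
class Match:
    """A single rule firing within one sentence.

    ``span`` is relative to the sentence text; ``groups`` carries captured
    substrings (e.g. the ASPECTS integer).
    """

    rule_id: str
    sentence_index: int
    span: tuple[int, int]
    groups: tuple[Optional[str], ...] = ()


@dataclass
class ScoreBundle:
    """Aggregated evidence for one attribute of one report.

    ``scores[c]`` is the sum of the weights of the listed matches whose
    rule targets class ``c``. For binary attributes ``probability`` is
    ``1 / (1 + exp(-scores['present']))``; zero evidence gives 0.5.
    """

    attribute: str
    scores: dict[str, float]
    probability: Optional[float]
    matches: list[Match] = field(default_factory=list)


@dataclass
class Prediction:
    """Per-attribute classification of one report, with full rule trace."""

    report_id: str
    classes: dict[str, str]
    bundles: dict[str, ScoreBundle]
    aspects_value: Optional[int] = None

    def to_json_obj(self) -> dict:
        obj: dict = {
            "id": self.report_id,
            "pred": dict(self.classes),
            "scores": {a: dict(b.scores) for a, b in self.bundles.items()},
        }
        if self.aspects_value is not None:
            obj["aspects_value"] = self.aspects_value
        return obj


class RuleSet:
    """An immutable collection of compiled rules grouped by attribute."""

    def __init__(self, compiled: Sequence[_CompiledRule]):
        self._compiled = tuple(compiled)
        self._by_attr: dict[str, list[_CompiledRule]] = {}
        self._by_id: dict[str, _CompiledRule] = {}
        for cr in self._compiled:
            self._by_attr.setdefault(cr.rule.attribute, []).append(cr)
            self._by_id[cr.rule.rule_id] = cr

    def __len__(self) -> int:
        return len(self._compiled)

    def __iter__(self):
        return iter(self._compiled)

    @property
    def rules(self) -> tuple[Rule, ...]:
        return tuple(cr.rule for cr in self._compiled)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self._by_attr)

    def for_attribute(self, attribute: str) -> tuple[_CompiledRule, ...]:
        return tuple(self._by_attr.get(attribute, ()))

    def get(self, rule_id: str) -> Rule:
        return self._by_id[rule_id].rule


RuleSource = Union[str, Path, Iterable[Union[Rule, Mapping]]]


def compile_ruleset(
    source: RuleSource,
    schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
) -> RuleSet:
    """Load, validate and compile a rule set.

    ``source`` is a path to a JSON file (a top-level list of rule objects
    with the :class:`Rule` fields) or an in-memory iterable of rules /
    rule dicts. Duplicate rule ids, zero weights, unknown attributes or
    classes, and malformed regular expressions are all rejected; regex
    errors name the offending rule_id.
    """
    if isinstance(source, (str, Path)):
        with Path(source).open("r", encoding="utf-8") as fh:
            raw = json.load(fh)
        if not isinstance(raw, list):
            raise RuleCompilationError("rule file must be a JSON list")
        items: Iterable = raw
    else:
        items = source

    compiled: list[_CompiledRule] = []
    seen_ids: set[str] = set()
    for item in items:
        rule = item if isinstance(item, Rule) else Rule(**dict(item))
        if rule.rule_id in seen_ids:
            raise RuleCompilationError(f"duplicate rule_id {rule.rule_id!r}")
        seen_ids.add(rule.rule_id)
        if rule.weight == 0:
            raise RuleCompilationError(f"rule {rule.rule_id!r}: weight must be non-zero")
        if rule.attribute not in schema:
            raise SchemaError(
                f"rule {rule.rule_id!r}: unknown attribute {rule.attribute!r}"
            )
        attr = schema[rule.attribute]
        if rule.target_class not in attr.classes:
            raise SchemaError(
                f"rule {rule.rule_id!r}: class {rule.target_class!r} "
                f"not in {attr.classes}"
            )
        flags = 0 if rule.case_sensitive else re.IGNORECASE
        try:
            regex = re.compile(rule.pattern, flags)
        except re.error as exc:
            raise RuleCompilationError(
                f"rule {rule.rule_id!r}: invalid pattern: {exc}"
            ) from exc
        compiled.append(_CompiledRule(rule=rule, regex=regex))
    return RuleSet(compiled)


def match_rules(ruleset: RuleSet, sentences: Sequence[Sentence]) -> list[Match]:
    """Match every rule against every sentence of one report.

    Each (rule, sentence) pair contributes at most one :class:`Match`, at
    the first match position; repeated occurrences of the same phrase in
    the same sentence are not double-counted.
    """
    matches: list[Match] = []
    for sentence in sentences:
        for cr in ruleset:
            m = cr.regex.search(sentence.text)
            if m is not None:
                matches.append(
                    Match(
                        rule_id=cr.rule.rule_id,
                        sentence_index=sentence.index,
                        span=m.span(),
                        groups=m.groups(),
                    )
                )
    return matches


def _logistic(s: float) -> float:
    # overflow-safe symmetric form
    if s >= 0:
        return 1.0 / (1.0 + math.exp(-s))
    z = math.exp(s)
    return z / (1.0 + z)


def score_attribute(
    matches: Sequence[Match],
    ruleset: RuleSet,
    attribute: str,
    schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
) -> ScoreBundle:
    """Sum signed rule weights into per-class scores for one attribute.

    Only matches whose rule targets ``attribute`` contribute. With no
    matches all scores are 0 and a binary probability is exactly 0.5.
    """
    attr = schema[attribute]
    scores: dict[str, float] = {c: 0.0 for c in attr.classes}
    kept: list[Match] = []
    for match in matches:
        rule = ruleset.get(match.rule_id)
        if rule.attribute != attribute:
            continue
        scores[rule.target_class] += rule.weight
        kept.append(match)
    probability = _logistic(scores[PRESENT]) if attr.is_binary else None
    return ScoreBundle(
        attribute=attribute, scores=scores, probability=probability, matches=kept
    )


def classify(bundle: ScoreBundle, attr: AttributeSchema) -> str:
    """Turn a score bundle into a class label.

    Binary: ``present`` iff the present-score is strictly positive, so a
    report with no evidence (score 0, probability 0.5) defaults to
    ``absent``. Categorical: among classes with strictly positive score,
    the highest wins, ties broken by the schema's worst-first priority;
    with no positive class the schema default wins.
    """
    if attr.is_binary:
        return PRESENT if bundle.scores[PRESENT] > 0 else ABSENT
    positive = [c for c in attr.classes if bundle.scores[c] > 0]
    if not positive:
        return attr.default_class
    best = max(bundle.scores[c] for c in positive)
    for c in attr.priority:
        if c in positive and bundle.scores[c] == best:
            return c
    raise AssertionError("unreachable: priority permutes classes")


#: ASPECTS mention with the score as an integer. Case-sensitive on the
#: capitalised token, so the anatomical homonym ("the lateral aspect of
#: the vessel") never fires.
ASPECTS_TOKEN_PATTERN = (
    r"\bASPECTS?\b\s*(?:score\s*)?(?:of|is|was|[:=\-])?\s*(\d{1,2})\b"
)
#: The spelled-out phrase "aspect score", matched case-insensitively.
ASPECT_SCORE_PATTERN = r"\baspect\s+score\b\s*(?:of|is|was|[:=\-])?\s*(\d{1,2})\b"

_FALLBACK_ASPECTS_REGEXES = (
    re.compile(ASPECTS_TOKEN_PATTERN),
    re.compile(ASPECT_SCORE_PATTERN, re.IGNORECASE),
)


def extract_aspects(
    sentences: Sequence[Sentence],
    ruleset: Optional[RuleSet] = None,
) -> tuple[str, Optional[int]]:
    """Extract the ASPECTS band and raw integer from segmented text.

    A valid mention requires the capitalised token ``ASPECTS``/``ASPECT``
    or the phrase "aspect score" (any case), followed by an integer in
    0–10; integers outside that range are ignored. The first valid mention
    in document order wins: value < 5 → ``lt5``, ≥ 5 → ``ge5``; no valid
    mention → (``not_reported``, None).

    When ``ruleset`` contains rules for the ``aspects`` attribute their
    patterns (each with the integer as capture group 1) replace the
    built-in pair, keeping the detector configurable as data.
    """
    if ruleset is not None and ruleset.for_attribute("aspects"):
        regexes = tuple(cr.regex for cr in ruleset.for_attribute("aspects"))
    else:
        regexes = _FALLBACK_ASPECTS_REGEXES
    for sentence in sentences:
        best_pos: Optional[int] = None
        best_value: Optional[int] = None
        for regex in regexes:
            for m in regex.finditer(sentence.text):
                try:
                    value = int(m.group(1))
                except (IndexError, TypeError, ValueError):
                    continue
                if not 0 <= value <= 10:
                    continue
                if best_pos is None or m.start() < best_pos:
                    best_pos, best_value = m.start(), value
                break  # later matches of the same pattern are never earlier
        if best_value is not None:
            return ("lt5" if best_value < 5 else "ge5"), best_value
    return NOT_REPORTED, None


def predict_report(
    report: Report,
    ruleset: RuleSet,
    schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> Prediction:
    """Run the full extraction pipeline on one report.

    Segments the text, matches all rules, scores and classifies the five
    binary findings and collateral status, and extracts ASPECTS via its
    mention detector. Deterministic: identical report and ruleset yield an
    identical prediction.
    """
    sentences = segment_sentences(report.text, report.id, abbreviations)
    matches = match_rules(ruleset, sentences)
    classes: dict[str, str] = {}
    bundles: dict[str, ScoreBundle] = {}
    for name, attr in schema.items():
        if name == "aspects":
            continue
        bundle = score_attribute(matches, ruleset, name, schema)
        classes[name] = classify(bundle, attr)
        bundles[name] = bundle
    aspects_class, aspects_value = extract_aspects(sentences, ruleset)
    aspects_matches = [
        m for m in matches if ruleset.get(m.rule_id).attribute == "aspects"
    ]
    bundles["aspects"] = ScoreBundle(
        attribute="aspects",
        scores={c: 0.0 for c in schema["aspects"].classes},
        probability=None,
        matches=aspects_matches,
    )
    classes["aspects"] = aspects_class
    return Prediction(
        report_id=report.id,
        classes=classes,
        bundles=bundles,
        aspects_value=aspects_value,
    )


def predict_corpus(
    reports: Sequence[Report],
    ruleset: RuleSet,
    schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
) -> list[Prediction]:
    """Predict every report of a corpus, order preserved."""
    return [predict_report(r, ruleset, schema) for r in reports]


def write_predictions(predictions: Iterable[Prediction], path: str | Path) -> None:
    """Write predictions as JSON-lines, one object per report."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for pred in predictions:
            fh.write(json.dumps(pred.to_json_obj(), ensure_ascii=False))
            fh.write("\n")


def read_predictions(path: str | Path) -> list[Prediction]:
    """Read a predictions JSON-lines file (class labels and scores only)."""
    out: list[Prediction] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            bundles = {
                attr: ScoreBundle(
                    attribute=attr,
                    scores={c: float(s) for c, s in scores.items()},
                    probability=None,
                    matches=[],
                )
                for attr, scores in obj.get("scores", {}).items()
            }
            out.append(
                Prediction(
                    report_id=str(obj["id"]),
                    classes=dict(obj["pred"]),
                    bundles=bundles,
                    aspects_value=obj.get("aspects_value"),
                )
            )
    return out
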