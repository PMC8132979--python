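"""Labeled synthetic CT/CTA/CTP report corpora.

The study corpus behind this pipeline (1320 consecutive stroke-protocol
imaging reports) is private, so this module emulates its statistical
structure: per-attribute prevalences matching the published cohort
(large vessel occlusion 12.2%, distal occlusion 14.2%, basilar occlusion
2.0%, established ischemia 29.6%, hemorrhage 10.5%, ASPECTS reported in
29.1% of reports with 40/384 of those below 5, collateral status reported
in 16.4% with good/intermediate/poor split 141/26/49), line-structured
report text rendered from a template bank in both spelling dialects, and
optional injection of the documented adversarial cases:

* ``negation_decoy`` — absent findings are explicitly negated rather than
  omitted ("No evidence of intracranial hemorrhage.");
* ``hedge_ischemia`` — ischemia stated with hedging language ("possible
  subtle hypodensity");
* ``ica_to_m2_extension`` — an occlusion running from the internal
  carotid artery to the M2 segment: truly a proximal occlusion, but no
  sentence ever says "M1" (engine-invisible, a false negative by design);
* ``cavernous_reconstitution`` — cavernous ICA near-occlusion with M1
  flow reconstituted: not a large vessel occlusion, but "occlusion" and
  "M1" share a sentence (a false positive by design);
* ``aspect_homonym`` — the anatomical word "aspect" appears without any
  score.

Gold labels always follow the generator's clinical ground truth, not what
the rule engine can recover, so the documented failure modes surface as
honest errors. Attributes are sampled independently (only marginal
prevalences are published). Generation is deterministic given the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .schema import (
    ABSENT,
    BINARY_ATTRIBUTES,
    NOT_REPORTED,
    PRESENT,
    Report,
    validate_labels,
)
from .stroke_rules import load_default_rules

__all__ = [
    "SimConfig",
    "ConfigError",
    "HARD_CASE_TAGS",
    "DEFAULT_PREVALENCE",
    "generate_corpus",
    "inject_hard_case",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


HARD_CASE_TAGS = (
    "negation_decoy",
    "hedge_ischemia",
    "ica_to_m2_extension",
    "cavernous_reconstitution",
    "aspect_homonym",
)

#: Published marginal prevalences of the five binary findings.
DEFAULT_PREVALENCE = {
    "lvo": 161 / 1320,
    "distal_occlusion": 188 / 1320,
    "basilar_occlusion": 26 / 1320,
    "ischemia": 391 / 1320,
    "hemorrhage": 139 / 1320,
}


@dataclass
class SimConfig:
    """Configuration of one synthetic corpus.

    Defaults reproduce the published cohort's attribute prevalences; all
    ``hard_rates`` default to 0 (a "clean" corpus the shipped rules can
    recover perfectly, since generator and rules share a cue vocabulary
    by construction).
    """

    n_reports: int = 1320
    seed: int = 0
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    aspects_reported: float = 384 / 1320
    p_lt5_given_reported: float = 40 / 384
    collaterals_reported: float = 216 / 1320
    collateral_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "good": 141 / 216,
            "intermediate": 26 / 216,
            "poor": 49 / 216,
        }
    )
    hard_rates: dict[str, float] = field(
        default_factory=lambda: {tag: 0.0 for tag in HARD_CASE_TAGS}
    )

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        probs = [
            *self.prevalence.values(),
            self.aspects_reported,
            self.p_lt5_given_reported,
            self.collaterals_reported,
            *self.collateral_class_probs.values(),
            *self.hard_rates.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if set(self.prevalence) != set(BINARY_ATTRIBUTES):
            raise ConfigError(
                f"prevalence must cover exactly {BINARY_ATTRIBUTES}"
            )
        if abs(sum(self.collateral_class_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("collateral class probabilities must sum to 1")
        unknown = set(self.hard_rates) - set(HARD_CASE_TAGS)
        if unknown:
            raise ConfigError(f"unknown hard-case tag(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# template bank — kept in lock-step with the default rule vocabulary
# ---------------------------------------------------------------------------

_SIDES = ("left", "right")

_HEADERS = (
    "CT HEAD, CT ANGIOGRAPHY AND CT PERFUSION OF THE HEAD AND NECK.",
    "CT AND CT ANGIOGRAPHY OF THE HEAD AND NECK.",
    "STROKE PROTOCOL CT OF THE HEAD AND NECK.",
)

_NEUTRAL = (
    "Study performed following administration of intravenous contrast.",
    "Comparison is made with the prior examination.",
    "The orbits and paranasal sinuses are unremarkable.",
)

_IMPRESSIONS = (
    "As described above.",
    "Findings discussed with the stroke team.",
)

_POSITIVE = {
    "lvo": (
        "Occlusion of the {side} M1 segment of the middle cerebral artery.",
        "There is loss of opacification of the {side} M1 segment.",
        "Acute thrombus within the {side} A1 segment of the anterior "
        "cerebral artery.",
        "Occlusion at the carotid terminus extending into the proximal MCA.",
    ),
    "distal_occlusion": (
        "Occlusion of a {side} M2 branch.",
        "There is a filling defect in the {side} M3 segment.",
        "Thrombus within the {side} A2 segment.",
        "Occlusion of a distal MCA branch.",
    ),
    "basilar_occlusion": (
        "Occlusion of the basilar artery.",
        "Thrombus within the mid basilar artery.",
    ),
    "ischemia": (
        "Established infarct in the {side} MCA territory.",
        "Hypodensity with loss of grey-white differentiation in the "
        "{side} insula.",
        "Established ischaemia involving the {side} frontal lobe.",
        "Hypoattenuation consistent with acute infarction in the {side} "
        "caudate head.",
    ),
    "hemorrhage": (
        "Acute intraparenchymal hemorrhage in the {side} basal ganglia.",
        "Subarachnoid haemorrhage within the {side} sylvian fissure.",
        "A small subdural hematoma overlies the {side} convexity.",
    ),
}

_NEGATED = {
    "lvo": (
        "The M1 and A1 segments are patent.",
        "No occlusion of the M1 or A1 segments is identified.",
        "No evidence of occlusion at the carotid terminus.",
    ),
    "distal_occlusion": (
        "No occlusion of the M2 or M3 segments.",
        "The M2 and A2 segments are patent.",
    ),
    "basilar_occlusion": (
        "The basilar artery is patent.",
        "No evidence of basilar occlusion.",
    ),
    "ischemia": (
        "No evidence of acute ischemia.",
        "No acute infarct or hypodensity.",
    ),
    "hemorrhage": (
        "No evidence of intracranial hemorrhage.",
        "No acute intracranial haemorrhage.",
    ),
}

_HEDGED_ISCHEMIA = (
    "Possible subtle hypodensity in the {side} insular cortex.",
    "Cannot rule out early ischemia in the {side} MCA territory.",
)

_ASPECTS_TEMPLATES = (
    "ASPECTS is {value}.",
    "ASPECTS of {value}.",
    "The aspect score is {value}.",
)

_COLLATERAL_TEMPLATES = {
    "good": (
        "Good collateral circulation is noted.",
        "Collateral status is good.",
    ),
    "intermediate": (
        "Collateral supply is intermediate.",
        "Moderate collateral circulation is present.",
    ),
    "poor": (
        "Poor collateral circulation is noted.",
        "Collaterals are poor.",
    ),
}

_ICA_TO_M2_SENTENCE = (
    "There is an occlusion extending from the internal carotid artery to "
    "the M2 segment."
)
_CAVERNOUS_SENTENCE = (
    "Near-occlusion of the cavernous internal carotid artery with "
    "reconstitution of flow in the M1 segment."
)
_HOMONYM_SENTENCE = (
    "Calcification along the lateral aspect of the cavernous carotid artery."
)


def _render(template: str, rng: random.Random) -> str:
    if "{side}" in template:
        return template.format(side=rng.choice(_SIDES))
    return template


def _sample_labels(config: SimConfig, rng: random.Random) -> dict[str, str]:
    labels: dict[str, str] = {}
    for attr in BINARY_ATTRIBUTES:
        labels[attr] = (
            PRESENT if rng.random() < config.prevalence[attr] else ABSENT
        )
    if rng.random() < config.aspects_reported:
        labels["aspects"] = (
            "lt5" if rng.random() < config.p_lt5_given_reported else "ge5"
        )
    else:
        labels["aspects"] = NOT_REPORTED
    if rng.random() < config.collaterals_reported:
        classes = list(_COLLATERAL_TEMPLATES)
        weights = [config.collateral_class_probs[c] for c in classes]
        labels["collaterals"] = rng.choices(classes, weights=weights, k=1)[0]
    else:
        labels["collaterals"] = NOT_REPORTED
    return labels


def _render_report(
    report_id: str,
    labels: dict[str, str],
    config: SimConfig,
    rng: random.Random,
) -> Report:
    lines = [rng.choice(_HEADERS), "FINDINGS:", rng.choice(_NEUTRAL)]
    decoy_rate = config.hard_rates.get("negation_decoy", 0.0)
    decoy_used = False
    for attr in BINARY_ATTRIBUTES:
        if labels[attr] == PRESENT:
            lines.append(_render(rng.choice(_POSITIVE[attr]), rng))
        elif rng.random() < decoy_rate:
            lines.append(_render(rng.choice(_NEGATED[attr]), rng))
            decoy_used = True
    if labels["aspects"] != NOT_REPORTED:
        value = rng.randint(0, 4) if labels["aspects"] == "lt5" else rng.randint(5, 10)
        lines.append(rng.choice(_ASPECTS_TEMPLATES).format(value=value))
    if labels["collaterals"] != NOT_REPORTED:
        lines.append(rng.choice(_COLLATERAL_TEMPLATES[labels["collaterals"]]))
    lines += ["IMPRESSION:", rng.choice(_IMPRESSIONS)]
    return Report(
        id=report_id,
        text="\n".join(lines),
        labels=validate_labels(labels),
        hard_flags=["negation_decoy"] if decoy_used else [],
    )


_ATTRIBUTE_RULES = None


def _rules_for(attribute: str):
    # lazily compiled default rules, reused to locate finding sentences
    global _ATTRIBUTE_RULES
    if _ATTRIBUTE_RULES is None:
        _ATTRIBUTE_RULES = load_default_rules()
    return _ATTRIBUTE_RULES.for_attribute(attribute)


def _drop_lines(text: str, attributes: Sequence[str]) -> str:
    """Remove lines on which any rule of the given attributes fires."""
    rules = [cr for attr in attributes for cr in _rules_for(attr)]
    kept = [
        line
        for line in text.split("\n")
        if not any(cr.regex.search(line) for cr in rules)
    ]
    return "\n".join(kept)


def _insert_finding(text: str, sentence: str) -> str:
    """Insert a finding line directly after the FINDINGS: header."""
    lines = text.split("\n")
    try:
        at = lines.index("FINDINGS:") + 1
    except ValueError:
        at = 0
    return "\n".join(lines[:at] + [sentence] + lines[at:])


def inject_hard_case(
    report: Report, case_tag: str, rng: random.Random
) -> Report:
    """Rewrite one report into an adversarial variant.

    Replaces the relevant finding sentence(s) with the adversarial
    phrasing, sets the gold label to the clinical ground truth of that
    phrasing, and appends ``case_tag`` to ``hard_flags``. Returns a new
    report; the input is not modified.
    """
    if case_tag not in HARD_CASE_TAGS:
        raise ConfigError(f"unknown hard-case tag {case_tag!r}")
    labels = dict(report.labels) if report.labels is not None else None
    text = report.text
    if case_tag == "ica_to_m2_extension":
        # a real proximal occlusion the engine cannot see: no M1 wording
        text = _drop_lines(text, ["lvo", "distal_occlusion"])
        text = _insert_finding(text, _ICA_TO_M2_SENTENCE)
        if labels is not None:
            labels["lvo"] = PRESENT
            labels["distal_occlusion"] = PRESENT
    elif case_tag == "cavernous_reconstitution":
        # not a proximal occlusion, but "occlusion" and "M1" co-occur
        text = _drop_lines(text, ["lvo"])
        text = _insert_finding(text, _CAVERNOUS_SENTENCE)
        if labels is not None:
            labels["lvo"] = ABSENT
    elif case_tag == "hedge_ischemia":
        text = _drop_lines(text, ["ischemia"])
        text = _insert_finding(text, _render(rng.choice(_HEDGED_ISCHEMIA), rng))
        if labels is not None:
            labels["ischemia"] = PRESENT
    elif case_tag == "aspect_homonym":
        text = _insert_finding(text, _HOMONYM_SENTENCE)
    elif case_tag == "negation_decoy":
        absent = [
            a
            for a in BINARY_ATTRIBUTES
            if labels is None or labels[a] == ABSENT
        ]
        if absent:
            attr = rng.choice(absent)
            text = _insert_finding(text, _render(rng.choice(_NEGATED[attr]), rng))
    return Report(
        id=report.id,
        text=text,
        labels=None if labels is None else validate_labels(labels),
        hard_flags=[*report.hard_flags, case_tag],
    )


def generate_corpus(config: SimConfig) -> list[Report]:
    """Generate a labeled synthetic corpus.

    Attributes are sampled independently per their configured
    prevalences; each report's text is rendered one sentence per line
    (header, FINDINGS, finding sentences, IMPRESSION). Hard cases other
    than ``negation_decoy`` (which acts during rendering) are injected
    per report with their configured rates, in the fixed tag order of
    :data:`HARD_CASE_TAGS`; the two proximal-occlusion cases
    (``ica_to_m2_extension``, ``cavernous_reconstitution``) are mutually
    exclusive within a report, so every flag stays consistent with the
    final text and gold label. Byte-identical output for identical
    config and seed.
    """
    config.validate()
    rng = random.Random(config.seed)
    width = len(str(config.n_reports))
    corpus: list[Report] = []
    for i in range(config.n_reports):
        report_id = f"syn-{i + 1:0{width}d}"
        labels = _sample_labels(config, rng)
        report = _render_report(report_id, labels, config, rng)
        lvo_case_applied = False
        for tag in HARD_CASE_TAGS:
            if tag == "negation_decoy":
                continue
            drawn = rng.random() < config.hard_rates.get(tag, 0.0)
            if not drawn:
                continue
            if tag in ("ica_to_m2_extension", "cavernous_reconstitution"):
                # mutually exclusive: the second would overwrite the
                # first's finding and gold, leaving a stale flag
                if lvo_case_applied:
                    continue
                lvo_case_applied = True
            report = inject_hard_case(report, tag, rng)
        corpus.append(report)
    return corpus
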