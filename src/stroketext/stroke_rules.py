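"""Default rule library for the seven stroke attributes.

The rules re-create the documented behaviour of an iteratively refined
clinical rule set rather than transcribing any particular deployment:

* an occlusion synonym (occlusion/occluded, loss of opacification, filling
  defect, thrombus) co-occurring in one sentence with proximal anatomy
  (M1, A1, carotid terminus, proximal MCA) marks a large vessel occlusion;
* isolated intracranial ICA occlusion is deliberately NOT a large vessel
  occlusion, so no rule fires on ICA wording alone;
* M2/M3/A2/A3 or "distal MCA/ACA" wording marks distal occlusion, and
  "basilar" plus an occlusion synonym marks basilar occlusion;
* hemorrhage accepts both spelling dialects (hemorrhage/haemorrhage) and
  the common synonyms (hematoma, SAH, intraparenchymal blood);
* ischemia cues (hypodensity, infarct, ischemia, loss of grey-white
  differentiation) carry weight +2 when stated firmly and +1 when hedged
  ("possible subtle hypodensity", "cannot rule out early ischemia");
* negation cues (no / no evidence of / without / patent) in the same
  sentence carry weight -4, so a single negation overrides up to two
  strong cues.

Because rules only see one sentence at a time, two failure modes are
reproduced on purpose: an occlusion word next to "M1 segment" fires even
when the occlusion is actually in the cavernous ICA with reconstituted M1
flow (a false positive), and an occlusion described as running from the
ICA to the M2 segment never mentions M1 and is missed (a false negative).
`behavioral_fixture_suite` freezes these and other canonical cases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rule_engine import (
    ASPECT_SCORE_PATTERN,
    ASPECTS_TOKEN_PATTERN,
    Rule,
    RuleSet,
    compile_ruleset,
)
from .schema import NOT_REPORTED, validate_labels

__all__ = [
    "RULE_LIBRARY_VERSION",
    "DEFAULT_RULES",
    "load_default_rules",
    "BehavioralFixture",
    "behavioral_fixture_suite",
]

RULE_LIBRARY_VERSION = "0.1.0"

# Weight convention: +1 weak/hedged cue, +2 strong cue, -4 negation, so a
# negation vetoes up to two strong cues in the same sentence.
W_WEAK, W_STRONG, W_NEG = 1.0, 2.0, -4.0

_OCCL = r"(?:occlu\w*|loss of opacification|filling defect|thromb\w*)"
_LVO_ANAT = (
    r"(?:\bM1\b|\bA1\b|carotid terminus|proximal\s+(?:MCA\b|middle cerebral artery))"
)
_DISTAL_ANAT = (
    r"(?:\bM2\b|\bM3\b|\bM4\b|\bA2\b|\bA3\b|"
    r"distal\s+(?:MCA\b|ACA\b|middle cerebral artery|anterior cerebral artery))"
)
_NEG = r"(?:\bno\b|no evidence of|without|negative for|\bpatent\b|\bpatency\b)"
_HEM = (
    r"(?:ha?emorrhag\w*|ha?ematoma\w*|\bSAH\b|subarachnoid blood|"
    r"intraparenchymal blood|intracranial blood)"
)
_ISCH = (
    r"(?:infarct\w*|ischa?emi\w*|hypodensit\w*|hypoattenuat\w*|"
    r"loss of (?:the )?gr[ae]y[-\s]white differentiation)"
)
_HEDGE = (
    r"(?:possibl\w*|questionable|cannot (?:rule out|exclude)|"
    r"may represent|subtle)"
)


def _co(*parts: str) -> str:
    """Same-sentence co-occurrence of all parts, in any order."""
    return "^" + "".join(f"(?=.*{p})" for p in parts)


DEFAULT_RULES: tuple[Rule, ...] = (
    # --- large vessel occlusion (proximal anterior circulation) ---
    Rule(
        "lvo_occl_proximal", "lvo", "present", _co(_OCCL, _LVO_ANAT), W_STRONG,
        note="occlusion synonym + M1/A1/carotid-terminus/proximal-MCA wording",
    ),
    Rule(
        "lvo_negated", "lvo", "present", _co(_NEG, _LVO_ANAT), W_NEG,
        note="negation or patency stated for proximal anatomy",
    ),
    # --- distal anterior circulation occlusion (M2/A2 or beyond) ---
    Rule(
        "distal_occl", "distal_occlusion", "present",
        _co(_OCCL, _DISTAL_ANAT), W_STRONG,
        note="occlusion synonym + M2/M3/A2/A3 or distal MCA/ACA wording",
    ),
    Rule(
        "distal_negated", "distal_occlusion", "present",
        _co(_NEG, _DISTAL_ANAT), W_NEG,
    ),
    # --- basilar occlusion ---
    Rule(
        "basilar_occl", "basilar_occlusion", "present",
        _co(_OCCL, r"basilar"), W_STRONG,
    ),
    Rule(
        "basilar_negated", "basilar_occlusion", "present",
        _co(_NEG, r"basilar"), W_NEG,
    ),
    # --- intracranial hemorrhage ---
    Rule("hem_cue", "hemorrhage", "present", _co(_HEM), W_STRONG,
         note="both spelling dialects; hematoma, SAH, parenchymal blood"),
    Rule("hem_negated", "hemorrhage", "present", _co(_NEG, _HEM), W_NEG),
    # --- established cerebral ischemia ---
    Rule(
        "isch_firm", "ischemia", "present",
        "^(?!.*" + _HEDGE + ")" + _co(_ISCH)[1:], W_STRONG,
        note="firm ischemia cue with no hedging language in the sentence",
    ),
    Rule(
        "isch_hedged", "ischemia", "present", _co(_HEDGE, _ISCH), W_WEAK,
        note="hedged phrasing (possible / subtle / cannot rule out)",
    ),
    Rule("isch_negated", "ischemia", "present", _co(_NEG, _ISCH), W_NEG),
    # --- collateral status ---
    Rule(
        "coll_good", "collaterals", "good",
        _co(r"collateral", r"(?:good|robust|excellent)"), W_STRONG,
    ),
    Rule(
        "coll_intermediate", "collaterals", "intermediate",
        _co(r"collateral", r"(?:intermediate|moderate)"), W_STRONG,
    ),
    Rule(
        "coll_poor", "collaterals", "poor",
        _co(r"collateral", r"(?:poor|sparse|scant|absent)"), W_STRONG,
    ),
    # --- ASPECTS mention detectors (value captured as group 1) ---
    Rule(
        "aspects_token", "aspects", NOT_REPORTED, ASPECTS_TOKEN_PATTERN,
        W_WEAK, case_sensitive=True,
        note="capitalised ASPECTS/ASPECT token; case sensitivity avoids the "
             "anatomical homonym 'aspect'",
    ),
    Rule(
        "aspects_phrase", "aspects", NOT_REPORTED, ASPECT_SCORE_PATTERN,
        W_WEAK,
        note="the spelled-out phrase 'aspect score', any case",
    ),
)


def load_default_rules() -> RuleSet:
    """Compile and return the shipped rule library.

    Every attribute has at least one positive-evidence rule and every
    binary attribute at least one negation rule.
    """
    return compile_ruleset(DEFAULT_RULES)


@dataclass(frozen=True)
class BehavioralFixture:
    """A frozen report text with gold labels and expected engine output.

    ``engine_agrees_with_gold`` marks whether the engine is *supposed* to
    reproduce the gold label: the documented false-positive and
    false-negative mechanisms are fixtures where it must not.
    """

    fixture_id: str
    text: str
    gold: dict[str, str]
    engine_expected: dict[str, str]
    tag: str

    @property
    def engine_agrees_with_gold(self) -> bool:
        return self.gold == self.engine_expected


def _fx(fixture_id, text, gold, engine, tag) -> BehavioralFixture:
    return BehavioralFixture(
        fixture_id=fixture_id,
        text=text,
        gold=validate_labels(gold),
        engine_expected=validate_labels(engine),
        tag=tag,
    )


def behavioral_fixture_suite() -> list[BehavioralFixture]:
    """Fixed report texts exercising every documented engine behaviour."""
    return [
        _fx(
            "fig1_revision",
            "CT ANGIOGRAPHY HEAD AND NECK.\nFINDINGS:\n"
            "Loss of opacification of the left M1 segment extending into "
            "the M2 segment.\nIMPRESSION:\nAcute left M1 occlusion.",
            {"lvo": "present", "distal_occlusion": "present"},
            {"lvo": "present", "distal_occlusion": "present"},
            "m1-wording-counts-without-mca-spelled-out",
        ),
        _fx(
            "fig2_false_positive",
            "There is near-occlusion of the cavernous internal carotid "
            "artery with reconstitution of flow in the M1 segment.",
            {"lvo": "absent"},
            {"lvo": "present"},
            "same-sentence-cooccurrence-false-positive",
        ),
        _fx(
            "fig3_false_negative",
            "There is an occlusion extending from the internal carotid "
            "artery to the M2 segment.",
            {"lvo": "present", "distal_occlusion": "present"},
            {"lvo": "absent", "distal_occlusion": "present"},
            "no-anatomy-knowledge-false-negative",
        ),
        _fx(
            "aspect_homonym",
            "Calcification along the lateral aspect of the cavernous "
            "carotid artery.",
            {"aspects": NOT_REPORTED},
            {"aspects": NOT_REPORTED},
            "aspect-homonym",
        ),
        _fx(
            "hedged_ischemia",
            "Possible subtle hypodensity in the right insular cortex.",
            {"ischemia": "present"},
            {"ischemia": "present"},
            "hedged-ischemia-weak-cue",
        ),
        _fx(
            "canonical_lvo",
            "Occlusion of the M1 segment of the right MCA.",
            {"lvo": "present"},
            {"lvo": "present"},
            "canonical-positive",
        ),
        _fx(
            "negated_hemorrhage",
            "No evidence of intracranial hemorrhage.",
            {"hemorrhage": "absent"},
            {"hemorrhage": "absent"},
            "negation-veto",
        ),
        _fx(
            "isolated_ica_exclusion",
            "Occlusion of the intracranial internal carotid artery without "
            "involvement of the M1 segment.",
            {"lvo": "absent"},
            {"lvo": "absent"},
            "isolated-ica-not-lvo",
        ),
        _fx(
            "basilar_thrombus",
            "Thrombus within the basilar artery.",
            {"basilar_occlusion": "present"},
            {"basilar_occlusion": "present"},
            "canonical-positive",
        ),
        _fx(
            "collaterals_good",
            "Good collateral circulation is noted.",
            {"collaterals": "good"},
            {"collaterals": "good"},
            "canonical-positive",
        ),
        _fx(
            "aspects_low",
            "ASPECTS of 3 with large MCA territory infarct.",
            {"aspects": "lt5", "ischemia": "present"},
            {"aspects": "lt5", "ischemia": "present"},
            "aspects-banding",
        ),
        _fx(
            "aspects_high",
            "No acute hemorrhage. ASPECTS is 8.",
            {"aspects": "ge5"},
            {"aspects": "ge5"},
            "aspects-banding",
        ),
        _fx(
            "aspects_out_of_range",
            "ASPECTS 12.",
            {"aspects": NOT_REPORTED},
            {"aspects": NOT_REPORTED},
            "out-of-range-guard",
        ),
        _fx(
            "patent_proximal_vessels",
            "The M1 and A1 segments are patent.",
            {"lvo": "absent"},
            {"lvo": "absent"},
            "clean-negation",
        ),
    ]
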