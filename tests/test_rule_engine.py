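import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stroketext import (
    Report,
    Rule,
    STROKE_SCHEMA,
    classify,
    compile_ruleset,
    extract_aspects,
    match_rules,
    predict_report,
    score_attribute,
    segment_sentences,
)
from stroketext.rule_engine import RuleCompilationError, _logistic
from stroketext.schema import SchemaError


def _rs(*rules):
    return compile_ruleset(rules)


def _rule(rule_id, pattern, weight, attribute="lvo", target="present", **kw):
    return Rule(rule_id, attribute, target, pattern, weight, **kw)


class TestCompileRuleset:
    def test_valid_rule_compiles(self):
        rs = _rs(_rule("r1", r"occlusion", 2.0))
        assert len(rs) == 1
        assert rs.get("r1").pattern == "occlusion"

    def test_malformed_regex_names_rule(self):
        with pytest.raises(RuleCompilationError, match="r_bad"):
            _rs(_rule("r_bad", "(", 1.0))

    def test_duplicate_rule_id_rejected(self):
        with pytest.raises(RuleCompilationError, match="duplicate"):
            _rs(_rule("r1", "a", 1.0), _rule("r1", "b", 1.0))

    def test_unknown_attribute_and_class_rejected(self):
        with pytest.raises(SchemaError):
            _rs(Rule("r1", "midline_shift", "present", "a", 1.0))
        with pytest.raises(SchemaError):
            _rs(Rule("r1", "lvo", "good", "a", 1.0))

    def test_zero_weight_rejected(self):
        with pytest.raises(RuleCompilationError, match="weight"):
            _rs(_rule("r1", "a", 0.0))

    def test_loads_from_json_file(self, tmp_path):
        path = tmp_path / "rules.json"
        path.write_text(
            '[{"rule_id": "r1", "attribute": "lvo", "target_class": '
            '"present", "pattern": "occlusion", "weight": 2.0}]'
        )
        assert len(compile_ruleset(path)) == 1


class TestMatchRules:
    def test_negation_phrase_matches(self):
        rs = _rs(_rule("neg", r"no evidence of", -4.0))
        sentences = segment_sentences("There is no evidence of occlusion.")
        assert len(match_rules(rs, sentences)) == 1

    def test_one_match_per_rule_and_sentence(self):
        rs = _rs(_rule("occ", r"occlusion", 2.0))
        sentences = segment_sentences("Occlusion occlusion occlusion.")
        matches = match_rules(rs, sentences)
        assert len(matches) == 1
        assert matches[0].span[0] == 0  # first position wins

    def test_case_sensitive_rule_skips_homonym(self):
        rs = _rs(_rule("asp", r"ASPECT", 1.0, case_sensitive=True))
        sentences = segment_sentences("the posterior aspect of the vessel")
        assert match_rules(rs, sentences) == []

    def test_case_insensitive_by_default(self):
        rs = _rs(_rule("occ", r"occlusion", 2.0))
        assert match_rules(rs, segment_sentences("OCCLUSION seen.")) != []


class TestScoring:
    def test_single_positive_weight(self):
        rs = _rs(_rule("r", r"occlusion of the m1", 2.0))
        sentences = segment_sentences("Occlusion of the M1 segment.")
        bundle = score_attribute(match_rules(rs, sentences), rs, "lvo")
        assert bundle.scores["present"] == 2.0
        assert bundle.probability == pytest.approx(0.8807970779778823)

    def test_negation_outweighs_cue(self):
        rs = _rs(
            _rule("pos", r"occlusion", 2.0), _rule("neg", r"\bno\b", -4.0)
        )
        sentences = segment_sentences("No occlusion of the M1 segment.")
        bundle = score_attribute(match_rules(rs, sentences), rs, "lvo")
        assert bundle.scores["present"] == -2.0
        assert bundle.probability == pytest.approx(0.11920292202211755)

    def test_no_matches_gives_half_probability(self):
        rs = _rs(_rule("r", r"occlusion", 2.0))
        bundle = score_attribute([], rs, "lvo")
        assert bundle.scores["present"] == 0.0
        assert bundle.probability == 0.5

    @settings(derandomize=True, max_examples=100)
    @given(s=hst.floats(-50, 50))
    def test_logistic_symmetry(self, s):
        assert _logistic(s) + _logistic(-s) == pytest.approx(1.0)
        # probability threshold agrees with the score sign at rule-weight
        # magnitudes (classification itself uses the raw score, so float
        # underflow at |s| ~ 1e-25 is immaterial)
        if abs(s) >= 1e-6:
            assert (_logistic(s) > 0.5) == (s > 0)


class TestClassify:
    def test_binary_positive_score(self):
        rs = _rs(_rule("r", "occlusion", 3.0))
        sents = segment_sentences("Occlusion.")
        bundle = score_attribute(match_rules(rs, sents), rs, "lvo")
        assert classify(bundle, STROKE_SCHEMA["lvo"]) == "present"

    def test_binary_zero_score_defaults_absent(self):
        rs = _rs(_rule("r", "occlusion", 3.0))
        bundle = score_attribute([], rs, "lvo")
        assert classify(bundle, STROKE_SCHEMA["lvo"]) == "absent"

    def test_categorical_tie_broken_worst_first(self):
        rs = _rs(
            Rule("g", "collaterals", "good", "alpha", 2.0),
            Rule("p", "collaterals", "poor", "beta", 2.0),
        )
        sents = segment_sentences("alpha beta.")
        bundle = score_attribute(match_rules(rs, sents), rs, "collaterals")
        assert bundle.scores == {
            "not_reported": 0.0, "poor": 2.0, "intermediate": 0.0, "good": 2.0
        }
        assert classify(bundle, STROKE_SCHEMA["collaterals"]) == "poor"

    def test_categorical_no_positive_score_defaults(self):
        rs = _rs(Rule("g", "collaterals", "good", "alpha", 2.0))
        bundle = score_attribute([], rs, "collaterals")
        assert classify(bundle, STROKE_SCHEMA["collaterals"]) == "not_reported"


class TestExtractAspects:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("ASPECTS is 8.", ("ge5", 8)),
            ("ASPECTS of 3 with large MCA territory infarct.", ("lt5", 3)),
            (
                "Calcification along the lateral aspect of the cavernous "
                "carotid.",
                ("not_reported", None),
            ),
            ("ASPECTS 12", ("not_reported", None)),
            ("The aspect score is 6.", ("ge5", 6)),
            ("ASPECT SCORE 4", ("lt5", 4)),
            ("ASPECTS is 10.", ("ge5", 10)),
            ("ASPECTS is 0.", ("lt5", 0)),
        ],
    )
    def test_banding_and_homonym_guard(self, text, expected):
        assert extract_aspects(segment_sentences(text)) == expected

    def test_first_valid_mention_wins(self):
        text = "ASPECTS 12 reported in error.\nASPECTS is 3. ASPECTS is 9."
        assert extract_aspects(segment_sentences(text)) == ("lt5", 3)


class TestPredictReport:
    def test_empty_text_all_defaults(self, default_rules):
        pred = predict_report(Report("r0", ""), default_rules)
        assert pred.classes == {
            "lvo": "absent",
            "distal_occlusion": "absent",
            "basilar_occlusion": "absent",
            "ischemia": "absent",
            "hemorrhage": "absent",
            "aspects": "not_reported",
            "collaterals": "not_reported",
        }
        assert pred.aspects_value is None

    def test_m1_wording_counts_without_mca_spelled_out(self, default_rules):
        pred = predict_report(
            Report("r1", "Occlusion of the M1 segment."), default_rules
        )
        assert pred.classes["lvo"] == "present"

    def test_cross_anatomy_false_negative(self, default_rules):
        pred = predict_report(
            Report(
                "r2",
                "There is an occlusion extending from the internal carotid "
                "artery to the M2 segment.",
            ),
            default_rules,
        )
        assert pred.classes["lvo"] == "absent"

    def test_sentence_scope_limitation(self, default_rules):
        """A cue and anatomy split across sentences never jointly match."""
        joint = predict_report(
            Report("a", "Occlusion is seen involving the M1 segment."),
            default_rules,
        )
        split = predict_report(
            Report("b", "Occlusion is seen.\nThe M1 segment is described."),
            default_rules,
        )
        assert joint.classes["lvo"] == "present"
        assert split.classes["lvo"] == "absent"

    def test_determinism(self, default_rules):
        report = Report("r", "Occlusion of the M1 segment. ASPECTS is 7.")
        assert predict_report(report, default_rules) == predict_report(
            report, default_rules
        )


class TestScoreProperties:
    def test_additivity_over_sentences(self, default_rules):
        """The report score equals the sum of per-sentence contributions."""
        s1 = "Occlusion of the M1 segment."
        s2 = "Thrombus at the carotid terminus."
        full = predict_report(Report("r", s1 + "\n" + s2), default_rules)
        part1 = predict_report(Report("r", s1), default_rules)
        part2 = predict_report(Report("r", s2), default_rules)
        assert full.bundles["lvo"].scores["present"] == pytest.approx(
            part1.bundles["lvo"].scores["present"]
            + part2.bundles["lvo"].scores["present"]
        )

    def test_monotonicity_appending_positive_sentence(self, default_rules):
        base = "No evidence of occlusion at the carotid terminus."
        extra = "Occlusion of the M1 segment."
        before = predict_report(Report("r", base), default_rules)
        after = predict_report(Report("r", base + "\n" + extra), default_rules)
        assert (
            after.bundles["lvo"].scores["present"]
            >= before.bundles["lvo"].scores["present"]
        )
        for attr in ("hemorrhage", "ischemia", "basilar_occlusion"):
            assert after.bundles[attr].scores == before.bundles[attr].scores
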