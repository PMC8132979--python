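"""Extract stroke attributes from one free-text report.

Builds a short CTA report, runs the shipped rule library over it and
prints the predicted class, score and probability per attribute, plus
the rule trace showing which pattern fired in which sentence.
"""

from stroketext import Report, load_default_rules, predict_report

report = Report(
    id="example-1",
    text=(
        "CT ANGIOGRAPHY HEAD AND NECK.\n"
        "FINDINGS:\n"
        "Loss of opacification of the left M1 segment extending into the "
        "M2 segment.\n"
        "No evidence of intracranial hemorrhage.\n"
        "ASPECTS is 6.\n"
        "Good collateral circulation is noted.\n"
        "IMPRESSION:\n"
        "Acute left M1 occlusion."
    ),
)

rules = load_default_rules()
prediction = predict_report(report, rules)

print(f"report {report.id}")
for attribute, cls in prediction.classes.items():
    bundle = prediction.bundles[attribute]
    prob = "" if bundle.probability is None else f"  p={bundle.probability:.3f}"
    print(f"  {attribute:18s} -> {cls:12s} scores={bundle.scores}{prob}")
print(f"  raw ASPECTS value: {prediction.aspects_value}")
print("\nrule trace (which pattern fired where):")
for attribute, bundle in prediction.bundles.items():
    for match in bundle.matches:
        print(
            f"  {match.rule_id:20s} sentence {match.sentence_index} "
            f"chars {match.span}"
        )
# A positive present-score means the weighted evidence favours the
# finding; 'no evidence of ...' sentences carry weight -4 and so override
# up to two strong (+2) cues in the same sentence.
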