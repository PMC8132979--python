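"""Author a custom rule file and run it instead of the shipped library.

Rules are plain JSON: a pattern, an attribute, a target class and a
signed weight. Here a two-rule set for hemorrhage is written to disk,
compiled (with validation - bad regexes are rejected by rule id) and
applied. Negative weights are negation rules: they lower the evidence
when they fire in the same sentence as a cue.
"""

import json
import tempfile
from pathlib import Path

from stroketext import Report, compile_ruleset, predict_report

rules_json = [
    {
        "rule_id": "hem_cue",
        "attribute": "hemorrhage",
        "target_class": "present",
        "pattern": r"ha?emorrhage|ha?ematoma",
        "weight": 2.0,
        "note": "both spelling dialects",
    },
    {
        "rule_id": "hem_negated",
        "attribute": "hemorrhage",
        "target_class": "present",
        "pattern": r"^(?=.*(?:\bno\b|no evidence of))(?=.*ha?emorrhage)",
        "weight": -4.0,
        "note": "same-sentence negation veto",
    },
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "rules.json"
    path.write_text(json.dumps(rules_json, indent=2))
    ruleset = compile_ruleset(path)
    print(f"compiled {len(ruleset)} rules for {ruleset.attributes}")

    for text in (
        "Acute subdural haematoma on the right.",
        "No evidence of intracranial hemorrhage.",
    ):
        pred = predict_report(Report("r", text), ruleset)
        score = pred.bundles["hemorrhage"].scores["present"]
        print(f"  {text!r} -> hemorrhage={pred.classes['hemorrhage']} (score {score:+.0f})")
# The first sentence scores +2 (cue) -> present; the second scores
# 2 - 4 = -2 (cue vetoed by negation) -> absent.
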