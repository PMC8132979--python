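"""Inject documented hard cases and review the resulting discrepancies.

Two adversarial phrasings are injected at 5% each: an occlusion running
from the internal carotid artery to the M2 segment (truly a proximal
occlusion, but no sentence says "M1" - a false negative by design) and a
cavernous ICA near-occlusion with reconstituted M1 flow (not a proximal
occlusion, but "occlusion" and "M1" share a sentence - a false positive
by design). The discrepancy report lists each mismatch with the rule
trace a reviewer would use to refine the rules.
"""

from stroketext import (
    SimConfig,
    confusion,
    discrepancy_report,
    generate_corpus,
    load_default_rules,
    predict_corpus,
)

config = SimConfig(
    n_reports=600,
    seed=11,
    hard_rates={"ica_to_m2_extension": 0.05, "cavernous_reconstitution": 0.05},
)
corpus = generate_corpus(config)
rules = load_default_rules()
predictions = predict_corpus(corpus, rules)

n_fn_flags = sum("ica_to_m2_extension" in r.hard_flags for r in corpus)
n_fp_flags = sum("cavernous_reconstitution" in r.hard_flags for r in corpus)
cm = confusion(
    [r.labels["lvo"] for r in corpus],
    [p.classes["lvo"] for p in predictions],
    "present",
)
print(f"injected: {n_fn_flags} ICA-to-M2 reports, {n_fp_flags} cavernous reports")
print(f"LVO confusion: tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn}")
print("(every false negative is an ICA-to-M2 report and every false")
print(" positive a cavernous report - the degradation is exactly controlled)")

records = discrepancy_report(corpus, predictions)
print(f"\n{len(records)} discrepancies; first three for review:")
for record in records[:3]:
    fired = [t["rule_id"] for t in record.trace] or ["<no rule fired>"]
    print(
        f"  {record.report_id}: {record.attribute} gold={record.gold} "
        f"predicted={record.predicted} via {fired}"
    )
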