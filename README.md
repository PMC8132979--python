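# stroketext

Rule-based extraction of stroke attributes from free-text neuroimaging
reports, with the diagnostic-accuracy machinery used to validate such a
pipeline and a synthetic report generator so everything is testable
without private clinical data.

## The problem

Detailed neurovascular findings — above all whether a patient has a
proximal large vessel occlusion (LVO), the lesion treatable by
endovascular thrombectomy — live in narrative CT / CT angiography / CT
perfusion reports. Collecting them at population scale normally means
manual chart abstraction at minutes per chart. `stroketext` automates
this with a transparent, auditable rule engine meant for stroke
surveillance and research data collection, **not** for interpreting
images: it can only recover what the radiologist wrote.

Seven attributes are extracted per report:

| attribute | type | classes |
|---|---|---|
| `lvo` | binary | occlusion of MCA‑M1 or ACA‑A1 (± carotid terminus); isolated intracranial ICA occlusion excluded |
| `distal_occlusion` | binary | M2/A2 segments or beyond |
| `basilar_occlusion` | binary | basilar artery occlusion |
| `ischemia` | binary | established cerebral ischemia |
| `hemorrhage` | binary | any intracranial hemorrhage |
| `aspects` | categorical | `not_reported` / `lt5` / `ge5` (ASPECTS banded) |
| `collaterals` | categorical | `not_reported` / `poor` / `intermediate` / `good` |

## The engine

Every rule is a regular expression applied **within a single sentence**
and carries a signed weight *w* toward one class of one attribute. Per
attribute the matched weights sum to a score *s<sub>c</sub>*; for binary
attributes the evidence is expressed as a probability through the
standard logistic,

> p = 1 / (1 + e<sup>−s_present</sup>),

and the finding is called present iff *s_present* > 0 (so p > 0.5). The
shipped library uses weights +1 (hedged cue), +2 (firm cue) and −4
(negation), so one "no evidence of …" vetoes up to two firm cues in the
same sentence. Sentence scope is both the mechanism and the documented
failure mode: "occlusion" next to "M1 segment" fires even when the
occlusion is in the cavernous ICA (false positive), while an occlusion
"extending from the internal carotid artery to the M2 segment" never
says M1 and is missed (false negative). Both behaviours are frozen as
fixtures and reproduced by the synthetic generator's hard cases.

Validation mirrors a chart-abstraction study: per attribute a 2×2
confusion matrix against gold labels yields sensitivity, specificity,
PPV, NPV and accuracy (one-vs-rest per class for the two categorical
gradings), and every gold/prediction mismatch is surfaced as a
discrepancy record carrying the matched-rule trace for iterative rule
refinement.

## Worked example

```python
from stroketext import Report, load_default_rules, predict_report

report = Report(id="example-1", text=(
    "FINDINGS:\n"
    "Loss of opacification of the left M1 segment extending into the M2 segment.\n"
    "No evidence of intracranial hemorrhage.\n"
    "ASPECTS is 6."
))
pred = predict_report(report, load_default_rules())
for attribute in ("lvo", "distal_occlusion", "hemorrhage", "aspects"):
    bundle = pred.bundles[attribute]
    print(attribute, pred.classes[attribute], bundle.scores)
```

prints

```
lvo present {'present': 2.0, 'absent': 0.0}
distal_occlusion present {'present': 2.0, 'absent': 0.0}
hemorrhage absent {'present': -2.0, 'absent': 0.0}
aspects ge5 {'not_reported': 0.0, 'lt5': 0.0, 'ge5': 0.0}
```

The first sentence contains an occlusion synonym ("loss of
opacification") with both M1 (proximal, +2 → present) and M2 (distal,
+2 → present); the hemorrhage cue is vetoed by its same-sentence
negation (2 − 4 = −2 → absent); the ASPECTS detector reads the integer 6
and bands it as ≥5.

The `examples/` scripts walk through each capability: single-report
extraction with rule traces (`01`), a full simulate → split → extract →
evaluate study on a 1320-report synthetic corpus (`02`), hard-case
injection and discrepancy review (`03`), and authoring custom rule files
(`04`).

## Synthetic corpora

`SimConfig` / `generate_corpus` render labeled line-structured reports
from a template bank at configurable attribute prevalences (defaults
match a published tertiary-stroke-centre cohort of 1320 reports: LVO
12.2%, distal 14.2%, basilar 2.0%, ischemia 29.6%, hemorrhage 10.5%,
ASPECTS reported 29.1%, collaterals reported 16.4%). Adversarial
phrasings — explicit negations, hedged ischemia, the two proximal-
occlusion traps, the ASPECT/aspect homonym — are injected at
configurable rates, with gold labels always following clinical ground
truth so engine failures surface as honest errors. Generation is
byte-reproducible given the seed.

## Acceptance script

`scripts/acceptance.py` replays the whole pipeline end to end — it
generates a 1320-report corpus at the default prevalences, splits it
921/399, extracts all attributes with the shipped rules and evaluates
both cohorts — then recomputes the eight published prevalence and
missingness percentages from their numerator/denominator pairs via the
package's `prevalence` operation and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
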