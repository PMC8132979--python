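# Methods

## Model

`stroketext` classifies seven stroke attributes of a free-text
neuroimaging report with sentence-scoped weighted regular expressions.
The pipeline is: segment the report into sentences; match every rule
against every sentence (at most one match per rule per sentence);
per attribute, sum the signed weights of matched rules into per-class
scores; classify.

For a binary attribute with present-score *s*, the evidence is mapped to
a probability p = 1/(1+e^−s) and the finding is called present iff
*s* > 0 strictly (equivalently p > 0.5). The logistic is a design
choice: the underlying requirement is only that positive-weight rules
raise and negative-weight rules lower an evidence estimate, and the
logistic is the minimal monotone, symmetric (p(s)+p(−s)=1) mapping with
a natural 0.5 neutral point at zero evidence. The strict inequality
makes a report with no evidence — or exactly balanced evidence — default
to absent, the clinically conservative screening behaviour.

For a categorical attribute, each class accumulates its own score; among
classes with strictly positive score the maximum wins, ties broken by a
fixed worst-first priority (`poor` before `intermediate` before `good`;
`lt5` before `ge5`), and with no positive class the default
(`not_reported`) wins. Worst-first tie-breaking is clinical conservatism;
nothing in the validated workflow depends on it beyond determinism.

ASPECTS is modeled as the three-class band actually evaluated in chart
abstraction (`not_reported` / `<5` / `≥5`), not the raw 0–10 integer;
the integer is retained in the prediction (`aspects_value`) for the
trace. Its detector is not weight-based: a mention requires either the
capitalised token `ASPECTS`/`ASPECT` (case-sensitive, so the anatomical
homonym "the lateral aspect of the vessel" can never fire) or the
spelled-out phrase "aspect score" (any case), followed by an integer;
integers outside 0–10 are ignored and the first valid mention in
document order wins (reports state the score once; multiplicity handling
is otherwise arbitrary).

## Assumptions and known limitations

* **Sentence scope.** A rule can never combine evidence across
  sentences. This reproduces, deliberately, two failure modes: a false
  positive when an occlusion word and "M1 segment" co-occur in a
  sentence describing a cavernous-ICA near-occlusion with reconstituted
  M1 flow, and a false negative when a true proximal occlusion is
  described as "extending from the internal carotid artery to the M2
  segment" without the token M1. Both are frozen as behavioral fixtures
  and as synthetic hard cases; a green suite certifies the engine *has*
  these failure modes, not that it lacks them.
* **No anatomy ontology, no coreference, no learned weights.** The
  engine detects keywords; it does not know that ICA→M2 implies M1.
* **Hedging.** Firm ischemia cues weigh +2, hedged phrasings ("possible
  subtle hypodensity", "cannot rule out early ischemia") weigh +1, so a
  hedge alone classifies present unless any negation fires. Whether
  hedged language *should* count as positive is genuinely ambiguous —
  human abstractors agree only ~80% on ischemia — so the package fixes a
  convention (hedge ⇒ present, and the synthetic generator assigns gold
  `present` to hedged-ischemia reports) rather than pretending the
  ambiguity away. Flip the convention by re-weighting `isch_hedged`.

## Rule weights

Shipped magnitudes are {1 weak cue, 2 strong cue, 4 negation}: a single
same-sentence negation ("no evidence of…", "without", "patent")
overrides up to two strong cues. This encodes the veto semantics of
negation in radiology prose; the absolute scale is immaterial (only
signs and ratios matter to classification), which is why no attempt is
made to calibrate the logistic probabilities.

## Sentence segmentation

Newlines are hard boundaries (radiology reports are line-structured,
with section headers like `FINDINGS:` on their own lines). Within a
line, a sentence ends at a run of `.!?` followed by whitespace and an
uppercase letter or digit. Periods inside decimals ("1.5 cm") are never
followed by whitespace and thus never split; a configurable abbreviation
list (Dr, vs, e.g, i.e, approx, …) protects the rest. Offsets are
0-based half-open so `text[start:end] == sentence.text` exactly, and
sentences plus the removed whitespace delimiters tile the input — a
property tested on random texts. No claim of behavioural equivalence
with any other segmenter is made; the splitter is deliberately simple
and its dialect is configuration.

## Evaluation

Standard report-level definitions: sensitivity 100·tp/(tp+fn),
specificity 100·tn/(tn+fp), PPV 100·tp/(tp+fp), NPV 100·tn/(tn+fn),
accuracy 100·(tp+tn)/n; categorical attributes get one-vs-rest rows per
class plus a single exact-match overall accuracy. Zero-denominator
metrics are undefined and render "NA" — coercing them to 0 or 100 would
distort small-cell attributes like basilar occlusion. Values are kept
unrounded internally and rounded half-away-from-zero to one decimal only
at presentation. Inter-rater reliability is raw percent agreement (no
chance correction; kappa is out of scope). Train/validation splitting is
a seeded shuffle with |train| = round(fraction·n), materialised as
id-list files so cohort membership is auditable.

Published validation tables of this kind are not always internally
consistent under report-level counting (a prevalence/sensitivity/
specificity triple can force a PPV different from the printed one, e.g.
when occlusions are counted per-vessel but accuracy per-report); this
package implements the standard definitions and does not attempt to
reproduce such cells.

## Synthetic generator

The generator emulates the statistical structure of a 1320-report
tertiary-stroke-centre corpus: default marginal prevalences LVO
161/1320, distal 188/1320, basilar 26/1320, ischemia 391/1320,
hemorrhage 139/1320; ASPECTS reported 384/1320 with P(<5 | reported) =
40/384; collaterals reported 216/1320 split 141/26/49 over
good/intermediate/poor. Attributes are sampled independently — only
marginal prevalences are published, and inventing a correlation
structure would be worse than stating independence. Text is rendered one
sentence per line from a template bank written in neutral radiology
style with both spelling dialects (hemorrhage/haemorrhage,
ischemia/ischaemia) represented.

The template vocabulary is intentionally the rule vocabulary: on a
"clean" corpus (all hard-case rates 0) the shipped rules recover every
gold label, which makes perfect recovery a *calibration* check of the
plumbing, not evidence about real-world accuracy. Real reports vary in
phrasing far beyond the bank; a green clean-corpus test establishes that
segmentation, matching, scoring, classification and evaluation compose
correctly, nothing more.

Hard cases are injected per report at configurable rates, with gold set
by clinical ground truth: `ica_to_m2_extension` (gold LVO present, and
gold distal present since the clot traverses M2; engine predicts LVO
absent), `cavernous_reconstitution` (gold LVO absent; engine predicts
present), `hedge_ischemia` (gold present; engine present via the +1
hedge), `aspect_homonym` (gold unchanged), `negation_decoy` (absent
findings explicitly negated instead of omitted; gold unchanged). The two
proximal-occlusion cases are mutually exclusive within one report —
applying both would overwrite the first one's finding sentence and gold,
leaving a stale flag — so the count of flagged reports equals the LVO
false-negative (resp. false-positive) count *exactly*, even when both
rates are non-zero. Injection rewrites the relevant finding lines by
locating them with the default rules themselves, which keeps template
and surgery in lock-step.

## Numerical and degenerate-input choices

* Logistic computed in the overflow-safe branch form; score 0 ⇒ p = 0.5
  exactly.
* Empty text segments to an empty list and classifies everything to its
  default class.
* One match per (rule, sentence), first position wins: repeated phrases
  cannot inflate scores.
* `round1` uses decimal half-away-from-zero (Python's banker rounding
  would turn 12.25 into 12.2).
* Seeds: one `random.Random(seed)` stream drives a whole corpus; the
  split uses its own seed. Identical (config, seed) ⇒ byte-identical
  outputs.

## What the tests establish

Unit and property tests cover each stage's contract (span tiling,
match caps, logistic symmetry, additivity, tie-breaks, metric formulas
against brute-force and scikit-learn recounts, split sizes and
determinism). The acceptance suite checks: exact prevalence arithmetic
on published numerator/denominator pairs; the frozen hard-case
behaviours; metric oracle equivalence at n=1000; 100% recovery on a
clean 1000-report corpus; exact controlled degradation under injected
hard cases; the 921/399 split contract; and generator calibration within
3 binomial standard errors at n=20 000. None of this certifies accuracy
on real clinical text, which requires validation against manually
abstracted reports from the target institution.
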