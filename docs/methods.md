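# Methods

## Problem and model

Head CT radiology reports describe acute intracranial pathology in short,
telegraphic prose. The package extracts that content in two stages, both
deterministic:

**Stage I — dictionary NER.** A lexicon maps lowercase surface terms
(single- or multi-word) to entities, and entities to one of five
categories: INJURY, MAGNITUDE, LOCATION, TIME, OTHER. OTHER entities carry
a functional subrole — NEGATION ("no", "without", "no evidence of"),
UNCERTAINTY ("possible", "likely", "cannot exclude"), or END_LINE ("'.'",
";"). Terms carry three boolean markers used downstream: `chronic_marker`
(longstanding disease: "atrophy", "small vessel ischemic disease", the time
term "chronic"), `recent_past_marker` ("evolving", "stable"), and
`extracranial_marker` (locations outside the skull: scalp, orbit, sinuses).
Numeric sizes are one pattern-typed term family (`<num> mm`, `<num> x
<num> cm`, ...) rather than an enumeration, because sizes are unbounded.

Matching is greedy leftmost-longest over token boundaries: scanning left to
right, the longest term starting at the current position is emitted and the
scan resumes at its end, so spans never overlap and "subdural hemorrhage"
beats "subdural" when both are in the dictionary. A match may not have a
word character immediately adjacent on either side ("hemorrhage" does not
fire inside "hemorrhages"); hyphens are non-word characters, so hyphenated
terms like "right-sided" match as whole tokens while plural handling is a
lexicon-content decision. Matching is case-insensitive and never crosses a
sentence boundary. The implementation compiles one alternation ordered by
token count then surface length, which realizes the longest-match rule at
each position; its correctness is checked against an independent
brute-force oracle that enumerates every candidate span and constructs the
leftmost-longest tiling explicitly.

Stage I is pluggable: anything implementing the `Tagger` callable protocol
(sentence → spans) can replace the dictionary matcher, e.g. an adapter
around a trained statistical model, without touching the decoder.

**Stage II — decoder.** Each report is reduced to one status per injury
category among POSITIVE > POSSIBLE > NEGATIVE > NOT_MENTIONED. There are 13
categories: hemorrhage, stroke, hydrocephalus, surgical_intervention,
herniation, mass_effect, midline_shift, edema, fluid, lesion,
pneumocephalus, vascular_malformation, density. Density subtypes (high /
low / mixed / undifferentiated) collapse into the single density category;
the subtype survives in the property summary.

Sentence rules, evaluated per injury span that carries a decoder group,
within the span's *scope* (the stretch between surrounding END_LINE spans;
an end-line term resets negation/uncertainty state):

1. chronic context (chronic-marked injury term, or a preceding
   chronic-marked TIME term in scope) → mention ignored, unless a
   recent-past marker is in scope, which forces POSITIVE;
2. an extracranial-marked LOCATION in scope → mention ignored;
3. a NEGATION span *before* the injury term in scope → NEGATIVE;
4. otherwise any UNCERTAINTY span in scope → POSSIBLE;
5. otherwise → POSITIVE.

Report labels start at NOT_MENTIONED and merge verdicts by precedence
maximum, so they are invariant to sentence order and monotone under adding
sentences. By default only FINDINGS / IMPRESSION sentences are decoded
(INTERPRETATION and CONCLUSION headers normalize to IMPRESSION); a report
with no recognized section headers is decoded in full, and gating can be
disabled outright.

### Committed readings where the rules are open

- **Negation scope is forward-only** within the END_LINE-delimited segment:
  "hemorrhage, not artifact" stays positive. This reading makes the
  "beforehand" condition literal and gives end-line terms a function.
- **Negation beats uncertainty**: POSSIBLE applies only when uncertainty is
  the sole modifier, so "no possible hemorrhage" is negative.
- **Uncertainty is direction-free** (before or after the injury term), since
  hedges commonly trail the finding ("hemorrhage cannot be excluded").
- **Chronic and extracranial suppression act at scope level** (a co-occurring
  modifier suppresses the mention), and the recent-past override outranks
  chronic suppression.
- A NEGATIVE verdict in FINDINGS can be upgraded by a later POSITIVE in
  IMPRESSION and vice versa — the merge is an order-independent maximum by
  design.

## Evaluation harness

- precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R); degenerate
  denominators report 0 with a warning so pooled evaluations stay total.
- **NER scoring is strict span match**: a true positive requires exact
  agreement on sentence, character offsets, and entity; partial overlaps and
  wrong types count one FP plus one FN. Strict matching is the harsher,
  unambiguous criterion. Aggregates are micro-averaged (pooled counts); a
  per-entity breakdown is also available.
- **Decoder scoring collapses NEGATIVE and NOT_MENTIONED** into one ABSENT
  class (a pertinent negative and a non-mention are equivalent at
  evaluation), then tallies one-vs-rest TP/FP/FN over the three classes,
  micro-pooled per category and overall.
- **Bootstrap CIs are percentile** (2.5th/97.5th of the statistic over
  seeded resamples with replacement), 1000 iterations by default, with the
  sentence as resampling unit for NER (5000 per resample) and the report for
  the decoder (100 per resample). BCa was not used; at these resample sizes
  the percentile method is adequate and simpler to reproduce.
- **Splits are patient-level**: patients are shuffled by seed and assigned
  whole to TRAIN until the training report count first reaches
  round-half-up(0.75 · N), the rest to TEST; 0.75 · 3361 = 2520.75 rounds to
  2521. K-fold (k = 10) partitions training patients into folds whose sizes
  differ by at most one. No report of a patient ever straddles a partition,
  avoiding within-person correlation.

## Synthetic report generator

The generator emulates the statistical structure of head CT reports, not
their prose. Sentences follow the template

    <negation?> <uncertainty?> <time?> <magnitude?> <location?> <injury> .

assembled from lexicon terms, wrapped in FINDINGS / IMPRESSION sections,
with exact gold offsets recorded at construction. Defaults: 500 reports,
3–8 sentences each, per-category prevalence 0.3, modifier rates (negation,
uncertainty, chronic, recent-past, extracranial) 0.2 per mention, optional
distractor filler tokens (default off), magnitude/location fill rates
0.5, acuity 0.3. Prevalence 0.3 keeps multi-injury reports common without
saturating every category; 0.2 modifier rates exercise every rule branch
frequently while leaving plain positive mentions the majority, which is the
regime these reports actually occupy.

Gold labels are derived inside the generator by a second, naive rule
evaluation (straight `if/elif` over the planted modifier booleans),
deliberately independent of the decoder module, so closed-loop tests compare
two separately written readings of the same rules rather than a function
with itself.

Two guards keep gold construction sound without consulting the tagger:
surfaces mapped to more than one entity are excluded from sampling pools,
and an assembled sentence is rejected (and resampled) if any token window
forms a lexicon surface that a leftmost-longest scan could actually reach
beyond the planted spans — e.g. a sampled location "intraventricular"
fusing with the following "hemorrhage" into the compound injury term. Both
checks use only the lexicon's surface set.

What passing closed-loop tests shows: the tagger and decoder implement the
stated matching and labelling semantics exactly on text whose structure the
lexicon covers. What it does not show: performance on real clinical prose —
free word order, coordination ("no hemorrhage or edema" is handled since
negation scopes forward, but "edema and hemorrhage are absent" is not),
misspellings, dictated artifacts, cross-sentence references. Real-corpus
accuracy is a property of lexicon coverage and must be established on real
data.

## The packaged default lexicon

The dictionary shape is fixed (5 categories, 64 entities, 469 terms, 13
decoder groups, the three OTHER subroles, the three term markers); the
concrete inventory was authored for this package by `scripts/
build_default_lexicon.py` and checked in as TSV. Entity names are
descriptive reconstructions (e.g. `subdural_space`, `interval_change`), not
canonical ontology identifiers; there is no UMLS/RadLex/SNOMED linking. Any
replacement lexicon with the same columns drops in via `load_lexicon`.

## Numerical and interface choices

- All text coordinates are 0-based half-open character offsets into the text
  the operation received; sentence spans index into the report, entity spans
  into their sentence.
- Sentence splitting is rule-based (terminal periods, semicolons, newlines)
  with decimal ("1.5 cm"), list-enumerator ("1."), and protected-abbreviation
  ("vs.", "cm.") guards — deterministic, no model dependencies.
- De-identification applies ordered regex rules against the original text
  (earlier rules claim characters first) and replaces matches with
  `[REDACTED:<class>]`; the packaged NAME/ID/DATE/PHONE/LOCATION rules are a
  configurable starting point, idempotent by construction, and not a
  certified de-identification guarantee.
- All randomness (simulation, splits, bootstrap) flows through
  `numpy.random.default_rng` seeds; identical config + seed gives
  byte-identical outputs.
- Degenerate inputs: empty corpora, empty lexicons, and empty reports are
  valid everywhere and produce empty outputs or all-NOT_MENTIONED summaries
  rather than errors.

## Problem sizes used in the shipped checks

Closed-loop recovery runs on 500 generated reports; oracle equivalence on
1000 random (sentence, mini-lexicon) instances with up to 12 tokens and 15
terms; bootstrap coverage on 200 replications of n = 5000 Bernoulli draws
with 1000 iterations each; the split check on 3361 single-report patients.
These sizes make every branch of the rule system and the arithmetic
observable while keeping the whole suite fast on one CPU.

## Known limitations

- No cross-sentence coreference ("it has enlarged"), no comparison of sizes
  between serial scans, no imaging-score computation (Marshall, Rotterdam,
  modified Fisher) — the decoder output is designed so such scores could be
  assembled downstream.
- Negation/uncertainty handling is scope-based, not syntactic; unusual
  constructions (post-posed negation, double negation) follow the committed
  readings above rather than a parse.
- The dictionary matcher cannot recognize out-of-lexicon synonyms or
  misspellings; statistical taggers can be substituted through the `Tagger`
  protocol but none is bundled.
- English only; single-report reasoning only.
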