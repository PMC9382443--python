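# headct-nlp

Rule-based extraction of acute brain injury findings from the free text of
noncontrast head CT radiology reports.

Radiology reports are the most widely available record of what a head CT
showed, but the findings are locked in prose. This package turns each report
into structured data in two deterministic stages:

1. **Dictionary NER tagger.** A gazetteer matcher over a clinical lexicon of
   469 terms grouped into 64 entities across five categories — injuries,
   magnitude, location, time, and other (negation, uncertainty, and end-line
   terms). Matching is greedy leftmost-longest on token boundaries and
   case-insensitive; numeric size terms ("5 mm", "1.5 cm", "3 x 4 mm") match
   through patterns. Output is a span list exportable in a two-column *long*
   format or a one-entity-per-column *wide* format.
2. **Rule-based decoder.** From the long-format spans, each report is
   summarized into a status label for each of 13 injury categories
   (hemorrhage, stroke, hydrocephalus, surgical intervention, herniation,
   mass effect, midline shift, edema, fluid, lesion, pneumocephalus,
   vascular malformation, density): **positive**, **possible**, **negative**,
   or **not mentioned**. Within a sentence, a preceding negation makes a
   mention negative; an uncertainty term alone makes it possible; chronic
   disease and extracranial findings are ignored, except that recent-past
   markers ("evolving", "stable") force positive. Across sentences the most
   positive mention wins: positive > possible > negative > not mentioned.

The package also ships the evaluation harness used to characterize such
pipelines — precision / recall / *F* (= 2PR/(P+R)) with percentile-bootstrap
95% CIs (1000 iterations; resampling 5000 sentences for NER, 100 reports for
the decoder), patient-level 75/25 train/test splitting and 10-fold
partitioning — plus a seeded synthetic report generator that produces
template-shaped CT sentences with gold spans and gold labels, so everything
is testable without protected health data.

The packaged lexicon is a working default authored for this implementation;
every term, marker, and decoder mapping is replaceable through a plain TSV
file (see `src/headct_nlp/data/default_lexicon.tsv`).

## Worked example

```python
import headct_nlp as h

report = h.RawReport(
    "ct_001", "patient_17",
    "FINDINGS: Acute right-sided 5 mm subdural hemorrhage. "
    "No evidence of midline shift.\n"
    "IMPRESSION: Possible mild cerebral edema. Chronic small vessel ischemic disease.",
)
lex = h.default_lexicon()
tagger = h.DictionaryTagger(lex)
sentences = h.sentences_of_report(report)
spans = [sp for s in sentences for sp in tagger.tag_sentence(s)]
print(h.to_long(spans).to_string(index=False))

kinds = {s.index: s.section_kind for s in sentences}
summary = h.decode_report(spans, lex, section_kinds=kinds)
for cat in h.DECODER_CATEGORIES:
    if summary.labels[cat] != h.InjuryStatus.NOT_MENTIONED:
        print(f"{cat:15s} {summary.labels[cat].name}")
print("properties:", summary.properties)
```

prints the long-format table

```
report_id  sentence_index  start                          text           entity
   ct_001               0      0                         Acute           acuity
   ct_001               0      6                   right-sided       laterality
   ct_001               0     18                          5 mm size_measurement
   ct_001               0     23                      subdural   subdural_space
   ct_001               0     32                    hemorrhage       hemorrhage
   ct_001               0     42                             .         end_line
   ct_001               1      0                No evidence of         negation
   ct_001               1     15                 midline shift    midline_shift
   ct_001               1     28                             .         end_line
   ct_001               2      0                      Possible      uncertainty
   ct_001               2      9                          mild         severity
   ct_001               2     14                cerebral edema            edema
   ct_001               2     28                             .         end_line
   ct_001               3      0                       Chronic       chronicity
   ct_001               3      8 small vessel ischemic disease  chronic_disease
   ct_001               3     37                             .         end_line
```

and the decoded report summary

```
hemorrhage      POSITIVE
midline_shift   NEGATIVE
edema           POSSIBLE
properties: {'hemorrhage': ['Acute', 'right-sided', '5 mm', 'subdural'], 'edema': ['mild']}
```

The subdural hemorrhage is positive and carries its co-sentential
descriptors (time, side, size, compartment); the explicit "no evidence of
midline shift" is a pertinent negative; the hedged edema is possible; the
chronic small-vessel disease is deliberately ignored; the other ten
categories stay not-mentioned.

## Command line

The same pipeline is available as `headct-nlp` with subcommands `deid`,
`tag`, `decode`, `eval`, `simulate`, and `query`, e.g.

```sh
headct-nlp simulate --n-reports 500 --seed 1 --out sim/
headct-nlp tag    --corpus sim/corpus.jsonl --out tagged/
headct-nlp decode --corpus sim/corpus.jsonl --out decoded/
headct-nlp eval   --corpus sim/corpus.jsonl --gold-spans sim/gold_spans.csv \
                  --gold-labels sim/gold_labels.csv --seed 1 --out eval/
headct-nlp query  --labels decoded/labels.csv \
                  --where stroke=POSITIVE --where edema=POSITIVE \
                  --where hemorrhage=absent --out hits/
```

Every run writes a `run_manifest.json` (version, seed, config hash); two
runs with the same config and seed produce byte-identical outputs.

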