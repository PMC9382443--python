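import itertools

import numpy as np
import pytest

from headct_nlp.decoder import (
    DecoderIntegrityError,
    InjuryStatus,
    QueryError,
    ReportSummary,
    decode_report,
    decode_sentence,
    labels_frame,
    query_cohort,
    summarize_cohort,
)
from headct_nlp.lexicon import DECODER_CATEGORIES
from headct_nlp.preprocess import Sentence


def spans_for(text, tagger, index=0, report_id="r1"):
    sent = Sentence(report_id, "FINDINGS", index, 0, len(text), text)
    return tagger.tag_sentence(sent)


# Each row: sentence text, expected {category: status} from that sentence
# alone (categories not listed must have no verdict).
RULE_TABLE = [
    # a negation before the injury term makes it negative
    ("no hemorrhage.", {"hemorrhage": InjuryStatus.NEGATIVE}),
    ("without midline shift.", {"midline_shift": InjuryStatus.NEGATIVE}),
    # an uncertainty term alone makes it possible (either side of the injury)
    ("possible edema.", {"edema": InjuryStatus.POSSIBLE}),
    ("hemorrhage cannot be excluded.", {"hemorrhage": InjuryStatus.POSSIBLE}),
    # no modifier at all: positive
    ("acute subdural hematoma.", {"hemorrhage": InjuryStatus.POSITIVE}),
    # recent-past markers label the injury positive
    ("stable hemorrhage.", {"hemorrhage": InjuryStatus.POSITIVE}),
    ("evolving infarct.", {"stroke": InjuryStatus.POSITIVE}),
    # chronic disease descriptions are ignored
    ("atrophy.", {}),
    ("small vessel ischemic disease.", {}),
    ("chronic infarct.", {}),
    # ... unless a recent-past marker overrides the chronic context
    ("chronic stable subdural hematoma.", {"hemorrhage": InjuryStatus.POSITIVE}),
    # injuries outside the skull are ignored
    ("scalp hematoma.", {}),
    ("subgaleal swelling and edema.", {}),
    # a preceding negation beats uncertainty ("uncertainty only" rule)
    ("no possible hemorrhage.", {"hemorrhage": InjuryStatus.NEGATIVE}),
    # negation is forward-only: it does not reach back
    ("hemorrhage, not artifact.", {"hemorrhage": InjuryStatus.POSITIVE}),
    # an end-line term resets negation/uncertainty scope
    ("no hemorrhage. edema.", {"hemorrhage": InjuryStatus.NEGATIVE,
                               "edema": InjuryStatus.POSITIVE}),
    ("possible infarct; hydrocephalus.", {"stroke": InjuryStatus.POSSIBLE,
                                          "hydrocephalus": InjuryStatus.POSITIVE}),
    # injury entities without a decoder group yield no verdict
    ("nasal bone fracture.", {}),
]


@pytest.mark.parametrize("text,expected", RULE_TABLE, ids=[r[0] for r in RULE_TABLE])
def test_sentence_rules(lex, tagger, text, expected):
    verdicts = decode_sentence(spans_for(text, tagger), lex)
    got = {}
    for v in verdicts:
        got[v.decoder_group] = max(got.get(v.decoder_group, InjuryStatus.NOT_MENTIONED),
                                   v.status)
    assert got == expected


def test_verdicts_cite_triggers_and_rules(lex, tagger):
    verdicts = decode_sentence(spans_for("no acute hemorrhage.", tagger), lex)
    assert len(verdicts) == 1
    v = verdicts[0]
    assert v.trigger.surface == "hemorrhage"
    assert v.rule_trace == ("negation_before",)
    assert v.supporting[0].surface == "no"


def test_density_subtypes_collapse_to_density(lex, tagger):
    for text in ("high density.", "hypodensity.", "mixed attenuation."):
        verdicts = decode_sentence(spans_for(text, tagger), lex)
        assert [v.decoder_group for v in verdicts] == ["density"]


class TestDecodeReport:
    def decode_two(self, lex, tagger, texts, kinds=None):
        spans = []
        for i, t in enumerate(texts):
            spans.extend(spans_for(t, tagger, index=i))
        return decode_report(spans, lex, section_kinds=kinds)

    def test_most_positive_mention_wins(self, lex, tagger):
        summary = self.decode_two(lex, tagger, ["No hemorrhage.", "Small acute hemorrhage."])
        assert summary.labels["hemorrhage"] == InjuryStatus.POSITIVE

    def test_negative_beats_not_mentioned(self, lex, tagger):
        summary = self.decode_two(lex, tagger, ["No hemorrhage."])
        assert summary.labels["hemorrhage"] == InjuryStatus.NEGATIVE

    def test_empty_report_all_not_mentioned(self, lex):
        summary = decode_report([], lex)
        assert set(summary.labels) == set(DECODER_CATEGORIES)
        assert all(v == InjuryStatus.NOT_MENTIONED for v in summary.labels.values())

    def test_single_possible_mention(self, lex, tagger):
        summary = self.decode_two(lex, tagger, ["possible stroke."])
        assert summary.labels["stroke"] == InjuryStatus.POSSIBLE
        others = [c for c in DECODER_CATEGORIES if c != "stroke"]
        assert all(summary.labels[c] == InjuryStatus.NOT_MENTIONED for c in others)

    def test_sentence_order_invariance(self, lex, tagger):
        texts = ["No hemorrhage.", "possible hemorrhage.", "evolving infarct.",
                 "chronic edema."]
        labels = None
        for perm in itertools.permutations(range(len(texts))):
            spans = []
            for i, j in enumerate(perm):
                spans.extend(spans_for(texts[j], tagger, index=i))
            got = decode_report(spans, lex).labels
            if labels is None:
                labels = got
            assert got == labels

    def test_monotonicity_adding_sentences(self, lex, tagger):
        texts = ["no hemorrhage.", "possible hemorrhage.", "acute hemorrhage."]
        prev = InjuryStatus.NOT_MENTIONED
        for k in range(1, len(texts) + 1):
            spans = []
            for i, t in enumerate(texts[:k]):
                spans.extend(spans_for(t, tagger, index=i))
            status = decode_report(spans, lex).labels["hemorrhage"]
            assert status >= prev
            prev = status

    def test_section_gating(self, lex, tagger):
        spans = spans_for("acute hemorrhage.", tagger, index=0)
        kinds = {0: "OTHER", 1: "FINDINGS"}
        spans += spans_for("mild edema.", tagger, index=1)
        summary = decode_report(spans, lex, section_kinds=kinds)
        assert summary.labels["hemorrhage"] == InjuryStatus.NOT_MENTIONED
        assert summary.labels["edema"] == InjuryStatus.POSITIVE

    def test_headerless_report_decodes_everything(self, lex, tagger):
        spans = spans_for("acute hemorrhage.", tagger, index=0)
        summary = decode_report(spans, lex, section_kinds={0: "OTHER"})
        assert summary.labels["hemorrhage"] == InjuryStatus.POSITIVE

    def test_section_gating_disabled(self, lex, tagger):
        spans = spans_for("acute hemorrhage.", tagger, index=0)
        kinds = {0: "OTHER", 1: "FINDINGS"}
        summary = decode_report(spans, lex, section_kinds=kinds, restrict_sections=False)
        assert summary.labels["hemorrhage"] == InjuryStatus.POSITIVE

    def test_rejects_mixed_reports(self, lex, tagger):
        spans = spans_for("edema.", tagger, report_id="a") + spans_for(
            "edema.", tagger, report_id="b"
        )
        with pytest.raises(DecoderIntegrityError):
            decode_report(spans, lex)

    def test_properties_collect_cosentential_modifiers(self, lex, tagger):
        spans = spans_for("acute right-sided 5 mm subdural hemorrhage.", tagger)
        summary = decode_report(spans, lex)
        assert summary.labels["hemorrhage"] == InjuryStatus.POSITIVE
        assert summary.properties["hemorrhage"] == ["acute", "right-sided", "5 mm", "subdural"]


def make_summary(report_id, **labels):
    s = ReportSummary(report_id=report_id)
    for cat, status in labels.items():
        s.labels[cat] = status
    return s


class TestCohort:
    def test_summarize_counts(self):
        cohort = [
            make_summary(f"r{i}", hemorrhage=InjuryStatus.POSITIVE) for i in range(3)
        ]
        table = summarize_cohort(cohort)
        assert list(table.loc["hemorrhage"]) == [3, 0, 0, 0]
        assert (table.sum(axis=1) == 3).all()

    def test_empty_cohort(self):
        table = summarize_cohort([])
        assert (table == 0).all().all() and len(table) == 13

    def test_mixed_statuses(self):
        cohort = [
            make_summary("a", stroke=InjuryStatus.POSITIVE),
            make_summary("b", stroke=InjuryStatus.NEGATIVE),
        ]
        assert list(summarize_cohort(cohort).loc["stroke"]) == [1, 0, 1, 0]

    def test_duplicate_report_rejected(self):
        with pytest.raises(DecoderIntegrityError):
            summarize_cohort([make_summary("a"), make_summary("a")])

    def test_query_toy_set(self):
        cohort = [
            make_summary("hit", stroke=InjuryStatus.POSITIVE, edema=InjuryStatus.POSITIVE),
            make_summary("m1", stroke=InjuryStatus.POSITIVE, edema=InjuryStatus.POSITIVE,
                         hemorrhage=InjuryStatus.POSITIVE),
            make_summary("m2", stroke=InjuryStatus.POSITIVE),
        ]
        got = query_cohort(
            cohort, {"stroke": "POSITIVE", "edema": "POSITIVE", "hemorrhage": "absent"}
        )
        assert got == ["hit"]

    def test_absent_accepts_explicit_negative(self):
        cohort = [make_summary("neg", hemorrhage=InjuryStatus.NEGATIVE)]
        assert query_cohort(cohort, {"hemorrhage": "absent"}) == ["neg"]

    def test_empty_predicate_matches_all(self):
        cohort = [make_summary("a"), make_summary("b")]
        assert query_cohort(cohort, {}) == ["a", "b"]

    def test_unknown_category_raises(self):
        with pytest.raises(QueryError, match="fracture"):
            query_cohort([make_summary("a")], {"fracture": "POSITIVE"})

    def test_labels_frame_layout(self):
        df = labels_frame([make_summary("a", edema=InjuryStatus.POSSIBLE)])
        assert list(df.columns) == ["report_id", *DECODER_CATEGORIES]
        assert df.iloc[0]["edema"] == "POSSIBLE"
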