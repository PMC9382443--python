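"""Rule-based decoding of tagged sentences into per-report injury labels.

Each report receives one status per injury category (hemorrhage, stroke,
hydrocephalus, surgical intervention, herniation, mass effect, midline
shift, edema, fluid, lesion, pneumocephalus, vascular malformation,
density), starting from NOT_MENTIONED defaults.

Sentence-level rules, applied to each injury span that carries a decoder
group, within the span's *scope* (the stretch between the surrounding
end-line spans of the sentence; an end-line term resets negation and
uncertainty state):

1. Chronic context (a chronic-marked injury term, or a preceding
   chronic-marked time term in scope) suppresses the mention — unless a
   recent-past marker ("evolving", "stable") is in scope, which forces
   POSITIVE.
2. An extracranial-marked location in scope suppresses the mention.
3. A negation span *before* the injury term in scope labels it NEGATIVE.
4. Otherwise, any uncertainty span in scope labels it POSSIBLE.
5. Otherwise the mention is POSITIVE.

Report-level merge is the precedence maximum: POSITIVE > POSSIBLE >
NEGATIVE > NOT_MENTIONED, so the most positive mention anywhere in the
decoded sections wins, independent of sentence order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .lexicon import DECODER_CATEGORIES, Lexicon
from .tagger import EntitySpan

#: Sections decoded by default; "interpretation"-style headers normalize to
#: IMPRESSION upstream.
DEFAULT_DECODED_SECTIONS = frozenset({"FINDINGS", "IMPRESSION"})


class InjuryStatus(IntEnum):
    """Report-level status of one injury category, ordered by precedence."""

    NOT_MENTIONED = 0
    NEGATIVE = 1
    POSSIBLE = 2
    POSITIVE = 3

    @staticmethod
    def merge(a: "InjuryStatus", b: "InjuryStatus") -> "InjuryStatus":
        return a if a >= b else b


@dataclass(frozen=True)
class SentenceVerdict:
    """The decoder's ruling on one injury mention."""

    report_id: str
    sentence_index: int
    decoder_group: str
    status: InjuryStatus
    trigger: EntitySpan
    supporting: tuple[EntitySpan, ...]
    rule_trace: tuple[str, ...]


@dataclass
class ReportSummary:
    """Per-report label vector over the 13 injury categories."""

    report_id: str
    labels: dict[str, InjuryStatus] = field(
        default_factory=lambda: {c: InjuryStatus.NOT_MENTIONED for c in DECODER_CATEGORIES}
    )
    #: for POSITIVE/POSSIBLE categories: magnitude/location/time surfaces
    #: co-sentential with the triggering injury spans
    properties: dict[str, list[str]] = field(default_factory=dict)
    verdicts: list[SentenceVerdict] = field(default_factory=list)


class DecoderIntegrityError(ValueError):
    pass


class QueryError(ValueError):
    pass


def _scopes(spans: Sequence[EntitySpan], lex: Lexicon) -> list[list[EntitySpan]]:
    """Partition a sentence's spans at END_LINE spans.

    The end-line span itself belongs to no scope; it only delimits.
    """
    scopes: list[list[EntitySpan]] = [[]]
    for span in sorted(spans, key=lambda s: s.start):
        entity = lex.entity(span.entity) if lex.has_entity(span.entity) else None
        if entity is not None and entity.subrole == "END_LINE":
            scopes.append([])
        else:
            scopes[-1].append(span)
    return [s for s in scopes if s]


def decode_sentence(spans: Sequence[EntitySpan], lex: Lexicon) -> list[SentenceVerdict]:
    """Apply the labelling rules to one sentence's spans.

    Spans must all come from one sentence; they are re-sorted by offset.
    Returns one verdict per non-suppressed injury mention that carries a
    decoder group.
    """
    verdicts: list[SentenceVerdict] = []
    for scope in _scopes(spans, lex):
        sub = {s: (lex.entity(s.entity).subrole if lex.has_entity(s.entity) else None)
               for s in scope}
        negations = [s for s in scope if sub[s] == "NEGATION"]
        uncertainties = [s for s in scope if sub[s] == "UNCERTAINTY"]
        recent_past = [s for s in scope if s.recent_past_marker]
        extracranial = [s for s in scope if s.extracranial_marker and s.category == "LOCATION"]
        for span in scope:
            if span.category != "INJURY":
                continue
            entity = lex.entity(span.entity)
            if entity.decoder_group is None:
                continue
            if entity.decoder_group not in DECODER_CATEGORIES:
                raise DecoderIntegrityError(
                    f"span {span.surface!r}: unknown decoder_group "
                    f"{entity.decoder_group!r}"
                )
            trace: list[str] = []
            chronic_context = span.chronic_marker or any(
                s.chronic_marker and s.category == "TIME" and s.start < span.start
                for s in scope
            )
            if chronic_context:
                if recent_past:
                    verdicts.append(
                        SentenceVerdict(
                            span.report_id,
                            span.sentence_index,
                            entity.decoder_group,
                            InjuryStatus.POSITIVE,
                            span,
                            tuple(recent_past),
                            ("chronic_context", "recent_past_override"),
                        )
                    )
                continue  # chronic description: ignored
            if extracranial:
                continue  # injury outside the skull: ignored
            preceding_neg = [s for s in negations if s.start < span.start]
            if preceding_neg:
                status = InjuryStatus.NEGATIVE
                support = tuple(preceding_neg)
                trace.append("negation_before")
            elif uncertainties:
                status = InjuryStatus.POSSIBLE
                support = tuple(uncertainties)
                trace.append("uncertainty_only")
            else:
                status = InjuryStatus.POSITIVE
                support = tuple(recent_past)
                trace.append("recent_past_positive" if recent_past else "plain_mention")
            verdicts.append(
                SentenceVerdict(
                    span.report_id,
                    span.sentence_index,
                    entity.decoder_group,
                    status,
                    span,
                    support,
                    tuple(trace),
                )
            )
    return verdicts


def decode_report(
    spans: Iterable[EntitySpan],
    lex: Lexicon,
    section_kinds: Optional[Mapping[int, str]] = None,
    decoded_sections: frozenset[str] = DEFAULT_DECODED_SECTIONS,
    restrict_sections: bool = True,
) -> ReportSummary:
    """Summarize one report's spans into the 13-category label vector.

    Parameters
    ----------
    spans
        All entity spans of one report (any sentence order).
    section_kinds
        Mapping sentence index -> section kind.  When provided and
        ``restrict_sections`` is true, only FINDINGS/IMPRESSION sentences are
        decoded — unless the report is headerless (no sentence in a decoded
        section kind), in which case all sentences are decoded.
    """
    spans = list(spans)
    report_ids = {s.report_id for s in spans}
    if len(report_ids) > 1:
        raise DecoderIntegrityError(f"spans from multiple reports: {sorted(report_ids)}")
    report_id = report_ids.pop() if report_ids else ""
    summary = ReportSummary(report_id=report_id)

    by_sentence: dict[int, list[EntitySpan]] = {}
    for s in spans:
        by_sentence.setdefault(s.sentence_index, []).append(s)

    gated = set(by_sentence)
    if restrict_sections and section_kinds is not None:
        in_scope = {i for i in by_sentence if section_kinds.get(i) in decoded_sections}
        headerless = not any(k in decoded_sections for k in section_kinds.values())
        if not headerless:
            gated = in_scope

    property_categories = ("MAGNITUDE", "LOCATION", "TIME")
    for idx in sorted(gated):
        sent_spans = sorted(by_sentence[idx], key=lambda s: s.start)
        for verdict in decode_sentence(sent_spans, lex):
            summary.verdicts.append(verdict)
            cat = verdict.decoder_group
            summary.labels[cat] = InjuryStatus.merge(summary.labels[cat], verdict.status)
            if verdict.status in (InjuryStatus.POSITIVE, InjuryStatus.POSSIBLE):
                props = [
                    s.surface for s in sent_spans if s.category in property_categories
                ]
                if props:
                    summary.properties.setdefault(cat, [])
                    for p in props:
                        if p not in summary.properties[cat]:
                            summary.properties[cat].append(p)
    # Properties only describe categories that ended up POSITIVE/POSSIBLE.
    summary.properties = {
        c: v
        for c, v in summary.properties.items()
        if summary.labels[c] in (InjuryStatus.POSITIVE, InjuryStatus.POSSIBLE)
    }
    return summary


def summarize_cohort(summaries: Sequence[ReportSummary]) -> pd.DataFrame:
    """13 x 4 contingency table of status counts over a cohort.

    Rows are the injury categories, columns the four statuses; each row sums
    to the cohort size.
    """
    seen: set[str] = set()
    for s in summaries:
        if s.report_id in seen:
            raise DecoderIntegrityError(f"duplicate report_id {s.report_id!r}")
        seen.add(s.report_id)
    statuses = ["POSITIVE", "POSSIBLE", "NEGATIVE", "NOT_MENTIONED"]
    data = {
        cat: [sum(1 for s in summaries if s.labels[cat].name == st) for st in statuses]
        for cat in DECODER_CATEGORIES
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=statuses)


def query_cohort(
    summaries: Sequence[ReportSummary], predicate: Mapping[str, str]
) -> list[str]:
    """Filter a cohort by a conjunction of category-status constraints.

    Constraint values are status names (``"POSITIVE"``, ...) or ``"absent"``,
    which is satisfied by NEGATIVE *and* NOT_MENTIONED (a pertinent negative
    and a non-mention are equivalent for exclusion queries).
    """
    valid = {s.name for s in InjuryStatus} | {"absent"}
    for cat, want in predicate.items():
        if cat not in DECODER_CATEGORIES:
            raise QueryError(f"unknown category {cat!r}")
        if want not in valid:
            raise QueryError(f"unknown status {want!r} for category {cat!r}")

    def matches(s: ReportSummary) -> bool:
        for cat, want in predicate.items():
            if want == "absent":
                if s.labels[cat] not in (InjuryStatus.NEGATIVE, InjuryStatus.NOT_MENTIONED):
                    return False
            elif s.labels[cat].name != want:
                return False
        return True

    return [s.report_id for s in summaries if matches(s)]


def labels_frame(summaries: Sequence[ReportSummary]) -> pd.DataFrame:
    """Decoder output table: report_id plus one status column per category."""
    rows = [
        {"report_id": s.report_id, **{c: s.labels[c].name for c in DECODER_CATEGORIES}}
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["report_id", *DECODER_CATEGORIES])
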