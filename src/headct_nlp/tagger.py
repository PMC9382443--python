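"""Deterministic dictionary NER over sentences, plus the long/wide exports.

Matching is greedy leftmost-longest over the lexicon's surfaces: scanning
left to right, the longest term starting at the current position wins and
the scan resumes after it, so emitted spans never overlap.  A match must
sit on token boundaries (no word character immediately adjacent on either
side), which keeps "hemorrhage" from firing inside "hemorrhages"; hyphens
inside terms ("right-sided") are handled by the term content itself.

Pattern-typed magnitude surfaces use the placeholder ``<num>``, which
matches an integer or decimal number token ("5 mm", "1.5 cm").

Any callable with the :class:`Tagger` signature can replace the dictionary
matcher (e.g. an adapter around a trained statistical model); everything
downstream consumes only :class:`EntitySpan` lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .lexicon import NUM_TOKEN, Lexicon, TermEntry
from .preprocess import Sentence

_NUM_RE = r"\d+(?:\.\d+)?"

LONG_COLUMNS = ["report_id", "sentence_index", "start", "text", "entity"]


@dataclass(frozen=True)
class EntitySpan:
    """One matched term occurrence within a sentence."""

    report_id: str
    sentence_index: int
    start: int  # offsets within the sentence text
    end: int
    surface: str
    entity: str
    category: str
    chronic_marker: bool = False
    recent_past_marker: bool = False
    extracranial_marker: bool = False


class Tagger(Protocol):
    """Anything that maps a sentence to entity spans."""

    def __call__(self, sent: Sentence, lex: Lexicon) -> list[EntitySpan]:
        ...


class SpanIntegrityError(ValueError):
    """Spans reference an unknown entity or overlap where they must not."""


def _surface_regex(surface: str) -> str:
    """Regex for one term surface: literal tokens, flexible whitespace,
    ``<num>`` placeholders, and token-boundary guards where the surface
    starts/ends with a word character."""
    parts = []
    for chunk in surface.split(" "):
        if chunk == NUM_TOKEN:
            parts.append(_NUM_RE)
        else:
            parts.append(re.escape(chunk).replace("<num>", _NUM_RE))
    body = r"\s+".join(parts)
    first = _NUM_RE if surface.startswith(NUM_TOKEN) else surface[:1]
    last = _NUM_RE if surface.endswith(NUM_TOKEN) else surface[-1:]
    prefix = r"(?<!\w)" if (first == _NUM_RE or re.match(r"\w", first)) else ""
    # A numeric tail must also not run into more digits ("5 cm" vs "5 cm2").
    suffix = r"(?!\w)" if (last == _NUM_RE or re.match(r"\w", last)) else ""
    return prefix + body + suffix


class DictionaryTagger:
    """Compiled greedy leftmost-longest matcher for one lexicon.

    Alternatives are ordered longest-surface-first so that, at each scan
    position, the regex engine's leftmost-alternative preference realizes
    the longest-match rule; ``finditer`` then yields the non-overlapping
    leftmost-longest tiling directly.
    """

    def __init__(self, lex: Lexicon):
        self.lexicon = lex
        # Longer surfaces first; word count then character count as proxy —
        # with <num> expanding, token count ordering is what matters at a
        # shared prefix.
        ordered = sorted(
            lex.terms, key=lambda t: (len(t.surface.split()), len(t.surface)), reverse=True
        )
        self._terms: list[TermEntry] = ordered
        if ordered:
            alternation = "|".join(
                f"(?P<t{i}>{_surface_regex(t.surface)})" for i, t in enumerate(ordered)
            )
            self._pattern = re.compile(alternation, re.IGNORECASE)
        else:
            self._pattern = None

    def __call__(self, sent: Sentence, lex: Lexicon | None = None) -> list[EntitySpan]:
        return self.tag_sentence(sent)

    def tag_sentence(self, sent: Sentence) -> list[EntitySpan]:
        if self._pattern is None or not sent.text:
            return []
        spans: list[EntitySpan] = []
        for m in self._pattern.finditer(sent.text):
            term = self._terms[int(m.lastgroup[1:])]
            spans.append(
                EntitySpan(
                    report_id=sent.report_id,
                    sentence_index=sent.index,
                    start=m.start(),
                    end=m.end(),
                    surface=sent.text[m.start(): m.end()],
                    entity=term.entity,
                    category=self.lexicon.category_of(term.entity),
                    chronic_marker=term.chronic_marker,
                    recent_past_marker=term.recent_past_marker,
                    extracranial_marker=term.extracranial_marker,
                )
            )
        return spans


def tag_sentence(sent: Sentence, lex: Lexicon) -> list[EntitySpan]:
    """Tag one sentence with a freshly compiled dictionary matcher.

    For corpus-scale work build one :class:`DictionaryTagger` and reuse it;
    this convenience wrapper recompiles the lexicon each call.
    """
    return DictionaryTagger(lex).tag_sentence(sent)


def tag_report(
    sentences: Sequence[Sentence], lex: Lexicon, tagger: Tagger | None = None
) -> list[EntitySpan]:
    """Tag every sentence of one report, preserving sentence order."""
    if tagger is None:
        tagger = DictionaryTagger(lex)
    spans: list[EntitySpan] = []
    for sent in sentences:
        spans.extend(tagger(sent, lex))
    return spans


# --------------------------------------------------------------------------
# Export formats
# --------------------------------------------------------------------------

def to_long(spans: Iterable[EntitySpan]) -> pd.DataFrame:
    """The two-column (text, entity) export, with provenance keys.

    One row per span, ordered by (report_id, sentence_index, start).
    """
    rows = [
        {
            "report_id": s.report_id,
            "sentence_index": s.sentence_index,
            "start": s.start,
            "text": s.surface,
            "entity": s.entity,
        }
        for s in spans
    ]
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    return df.sort_values(["report_id", "sentence_index", "start"], kind="stable").reset_index(
        drop=True
    )


def to_wide(
    spans: Iterable[EntitySpan], lex: Lexicon, delimiter: str = "|"
) -> pd.DataFrame:
    """The one-entity-per-column export: one row per tagged sentence.

    Cells hold the matched surface(s) for that entity in that sentence,
    multiple matches joined by ``delimiter``, empty string when absent.
    """
    entity_names = [e.name for e in lex.entities]
    known = set(entity_names)
    cells: dict[tuple[str, int], dict[str, list[str]]] = {}
    for s in sorted(spans, key=lambda s: (s.report_id, s.sentence_index, s.start)):
        if s.entity not in known:
            raise SpanIntegrityError(f"span references unknown entity {s.entity!r}")
        cells.setdefault((s.report_id, s.sentence_index), {}).setdefault(
            s.entity, []
        ).append(s.surface)
    rows = []
    for (rid, idx), per_entity in cells.items():
        row: dict[str, object] = {"report_id": rid, "sentence_index": idx}
        for name in entity_names:
            row[name] = delimiter.join(per_entity.get(name, []))
        rows.append(row)
    return pd.DataFrame(rows, columns=["report_id", "sentence_index"] + entity_names)


def render_annotated(sentence: Sentence, spans: Sequence[EntitySpan]) -> str:
    """Inline markup ``[surface|ENTITY]``; stripping it recovers the sentence."""
    ordered = sorted(spans, key=lambda s: s.start)
    prev_end = 0
    out: list[str] = []
    for s in ordered:
        if s.start < prev_end:
            raise SpanIntegrityError(
                f"overlapping spans at {s.start} in sentence {sentence.index}"
            )
        if not (0 <= s.start < s.end <= len(sentence.text)):
            raise SpanIntegrityError(f"span [{s.start},{s.end}) outside sentence")
        out.append(sentence.text[prev_end: s.start])
        out.append(f"[{sentence.text[s.start:s.end]}|{s.entity.upper()}]")
        prev_end = s.end
    out.append(sentence.text[prev_end:])
    return "".join(out)


def strip_annotation(marked: str) -> str:
    """Inverse of :func:`render_annotated`."""
    return re.sub(r"\[([^|\[\]]*)\|[A-Z0-9_]+\]", r"\1", marked)
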