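"""Synthetic head-CT-style report generator with gold spans and labels.

The generator emits short, template-shaped radiology sentences —

    <negation?> <uncertainty?> <time?> <magnitude?> <location?> <injury> .

— wrapped in FINDINGS / IMPRESSION sections, recording the exact character
offsets of every planted term (gold spans) and deriving the report-level
gold label for each injury category.  Templates are deliberately simple and
grammar-driven rather than realistic prose: the goal is controlled
statistical structure for testing, not realism.

Gold labels are derived here by a *second, naive* implementation of the
labelling rules (straight if/elif over the planted modifiers), independent
of the decoder module, so closed-loop tests compare two separately written
rule readings.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .decoder import InjuryStatus, ReportSummary, labels_frame
from .lexicon import DECODER_CATEGORIES, Lexicon, default_lexicon
from .preprocess import RawReport, Sentence, write_corpus
from .tagger import EntitySpan, to_long

_NUM_FULL = re.compile(r"\d+(?:\.\d+)?")


class GeneratorSpecError(ValueError):
    pass


@dataclass
class GeneratorSpec:
    """Configuration of a synthetic corpus.

    Rates are per injury mention; prevalence is per report and category.
    """

    n_reports: int = 500
    sentences_per_report: tuple[int, int] = (3, 8)
    prevalence: dict[str, float] = field(
        default_factory=lambda: {c: 0.3 for c in DECODER_CATEGORIES}
    )
    negation_rate: float = 0.2
    uncertainty_rate: float = 0.2
    chronic_rate: float = 0.2
    recent_past_rate: float = 0.2
    extracranial_rate: float = 0.2
    distractor_rate: float = 0.0
    magnitude_rate: float = 0.5
    location_rate: float = 0.5
    acuity_rate: float = 0.3
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_reports < 0:
            raise GeneratorSpecError("n_reports must be >= 0")
        lo, hi = self.sentences_per_report
        if not (1 <= lo <= hi):
            raise GeneratorSpecError("sentences_per_report must be a range 1 <= lo <= hi")
        rates = {
            "negation_rate": self.negation_rate,
            "uncertainty_rate": self.uncertainty_rate,
            "chronic_rate": self.chronic_rate,
            "recent_past_rate": self.recent_past_rate,
            "extracranial_rate": self.extracranial_rate,
            "distractor_rate": self.distractor_rate,
            "magnitude_rate": self.magnitude_rate,
            "location_rate": self.location_rate,
            "acuity_rate": self.acuity_rate,
            **{f"prevalence[{c}]": p for c, p in self.prevalence.items()},
        }
        for name, p in rates.items():
            if not 0.0 <= p <= 1.0:
                raise GeneratorSpecError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.prevalence) - set(DECODER_CATEGORIES)
        if unknown:
            raise GeneratorSpecError(f"unknown categories in prevalence: {sorted(unknown)}")


@dataclass
class GoldReport:
    report: RawReport
    sentences: list[Sentence]
    gold_spans: list[EntitySpan]
    gold_summary: ReportSummary


#: Filler vocabulary for distractor tokens and padding sentences; none of
#: these words occur in (or can join into) a default-lexicon surface — the
#: assembly guard below enforces that against whatever lexicon is in use.
_FILLER_WORDS = (
    "there", "is", "an", "area", "seen", "noted", "identified", "along",
    "adjacent", "overlying", "underlying", "appears", "appearing", "study",
    "examination", "visualized", "demonstrated", "redemonstrating",
)
_PAD_SENTENCES = (
    "study otherwise within normal limits",
    "visualized structures appear preserved",
    "examination is adequate",
    "remainder of the study is satisfactory",
)


class CorpusGenerator:
    """Seeded generator producing :class:`GoldReport` objects."""

    #: maximum token length of any lexicon surface considered by the
    #: accidental-match guard
    _MAX_WINDOW = 6

    def __init__(self, spec: GeneratorSpec, lexicon: Optional[Lexicon] = None):
        spec.validate()
        self.spec = spec
        self.lexicon = lexicon if lexicon is not None else default_lexicon()
        self.rng = np.random.default_rng(spec.seed)
        self._index_term_pools()
        self._surface_set = {
            t.surface for t in self.lexicon.terms if not t.is_pattern
        }
        self._pattern_set = {t.surface for t in self.lexicon.terms if t.is_pattern}

    # -- term pools ---------------------------------------------------------
    def _index_term_pools(self) -> None:
        lex = self.lexicon
        # Surfaces mapped to more than one entity are legal in a lexicon but
        # ambiguous as gold: keep them out of the sampling pools.
        surface_multiplicity = Counter(t.surface for t in lex.terms)
        lex_terms = [t for t in lex.terms if surface_multiplicity[t.surface] == 1]
        self._injury_terms: dict[str, list] = {c: [] for c in DECODER_CATEGORIES}
        for t in lex_terms:
            e = lex.entity(t.entity)
            if e.category == "INJURY" and e.decoder_group and not t.chronic_marker:
                self._injury_terms[e.decoder_group].append(t)
        self._negation = [
            t for t in lex_terms if lex.entity(t.entity).subrole == "NEGATION"
        ]
        self._uncertainty = [
            t for t in lex_terms if lex.entity(t.entity).subrole == "UNCERTAINTY"
        ]
        time_terms = [t for t in lex_terms if lex.category_of(t.entity) == "TIME"]
        self._chronic_time = [t for t in time_terms if t.chronic_marker]
        self._recent_past = [t for t in time_terms if t.recent_past_marker]
        self._acuity = [
            t for t in time_terms if not t.chronic_marker and not t.recent_past_marker
        ]
        loc_terms = [t for t in lex_terms if lex.category_of(t.entity) == "LOCATION"]
        self._intracranial_loc = [t for t in loc_terms if not t.extracranial_marker]
        self._extracranial_loc = [t for t in loc_terms if t.extracranial_marker]
        self._magnitude = [t for t in lex_terms if lex.category_of(t.entity) == "MAGNITUDE"]
        missing = [
            name
            for name, pool in [
                ("negation", self._negation),
                ("uncertainty", self._uncertainty),
                ("chronic time", self._chronic_time),
                ("recent-past time", self._recent_past),
                ("intracranial location", self._intracranial_loc),
                ("extracranial location", self._extracranial_loc),
                ("magnitude", self._magnitude),
            ]
            if not pool
        ]
        used = [c for c, p in self.spec.prevalence.items() if p > 0]
        missing += [f"injury[{c}]" for c in used if not self._injury_terms[c]]
        if missing:
            raise GeneratorSpecError(f"lexicon lacks terms for roles: {missing}")

    def _pick(self, pool: Sequence):
        return pool[int(self.rng.integers(0, len(pool)))]

    def _realize(self, term) -> str:
        """Surface string for a term; numeric placeholders get sampled values."""
        if not term.is_pattern:
            return term.surface
        out = []
        for tok in term.surface.split(" "):
            if tok == "<num>":
                if self.rng.random() < 0.5:
                    out.append(str(int(self.rng.integers(1, 30))))
                else:
                    out.append(f"{self.rng.integers(1, 9)}.{self.rng.integers(0, 9)}")
            else:
                out.append(tok)
        return " ".join(out)

    # -- sentence assembly --------------------------------------------------
    def _plan_mention(self, category: str) -> dict:
        """Sample the modifier structure of one injury mention."""
        rng = self.rng
        spec = self.spec
        plan = {
            "category": category,
            "injury": self._pick(self._injury_terms[category]),
            "negation": self._pick(self._negation) if rng.random() < spec.negation_rate else None,
            "uncertainty": self._pick(self._uncertainty)
            if rng.random() < spec.uncertainty_rate
            else None,
            "chronic": self._pick(self._chronic_time) if rng.random() < spec.chronic_rate else None,
            "recent_past": self._pick(self._recent_past)
            if rng.random() < spec.recent_past_rate
            else None,
            "magnitude": self._pick(self._magnitude) if rng.random() < spec.magnitude_rate else None,
        }
        if rng.random() < spec.extracranial_rate:
            plan["location"] = self._pick(self._extracranial_loc)
        elif rng.random() < spec.location_rate:
            plan["location"] = self._pick(self._intracranial_loc)
        else:
            plan["location"] = None
        if plan["chronic"] is None and plan["recent_past"] is None:
            plan["acuity"] = (
                self._pick(self._acuity) if rng.random() < spec.acuity_rate else None
            )
        else:
            plan["acuity"] = None
        return plan

    @staticmethod
    def _gold_status(plan: dict) -> Optional[InjuryStatus]:
        """Naive, decoder-independent label for one planted mention.

        Mirrors the stated labelling rules directly on the plan booleans:
        chronic context is ignored unless a recent-past marker forces
        positive; extracranial mentions are ignored; a preceding negation
        wins over uncertainty; uncertainty alone means possible.
        """
        if plan["chronic"] is not None:
            return InjuryStatus.POSITIVE if plan["recent_past"] is not None else None
        if plan["location"] is not None and plan["location"].extracranial_marker:
            return None
        if plan["negation"] is not None:
            return InjuryStatus.NEGATIVE
        if plan["uncertainty"] is not None:
            return InjuryStatus.POSSIBLE
        return InjuryStatus.POSITIVE

    def _assemble(self, plan: dict) -> tuple[str, list[tuple[int, int, object]]]:
        """Build sentence text and (start, end, term) triples, with optional
        distractor fillers between slots."""
        slots = []
        for key in ("negation", "uncertainty", "chronic", "recent_past", "acuity",
                    "magnitude", "location"):
            if plan[key] is not None:
                slots.append(plan[key])
        slots.append(plan["injury"])

        pieces: list[tuple[str, Optional[object]]] = []
        for term in slots:
            if self.spec.distractor_rate and self.rng.random() < self.spec.distractor_rate:
                n_fill = int(self.rng.integers(1, 3))
                for _ in range(n_fill):
                    pieces.append((self._pick(_FILLER_WORDS), None))
            pieces.append((self._realize(term), term))

        text_parts: list[str] = []
        triples: list[tuple[int, int, object]] = []
        cursor = 0
        for i, (surface, term) in enumerate(pieces):
            if i > 0:
                text_parts.append(" ")
                cursor += 1
            start = cursor
            text_parts.append(surface)
            cursor += len(surface)
            if term is not None:
                triples.append((start, cursor, term))
        text_parts.append(".")
        end_line = self._end_line_term()
        triples.append((cursor, cursor + 1, end_line))
        return "".join(text_parts), triples

    def _end_line_term(self):
        for t in self.lexicon.terms:
            if self.lexicon.entity(t.entity).subrole == "END_LINE" and t.surface == ".":
                return t
        raise GeneratorSpecError("lexicon lacks an end-line '.' term")

    def _has_accidental_match(
        self, text: str, triples: Sequence[tuple[int, int, object]]
    ) -> bool:
        """True if a leftmost-longest dictionary scan over this sentence could
        emit anything other than the planted spans.

        A non-planted token window that forms a lexicon surface is harmless
        when it can never be reached by the scan: windows starting strictly
        inside a planted span (the scan jumps over planted interiors), and
        shorter windows sharing a planted span's start (the longer planted
        match wins).  Everything else — a surface in open text (e.g. filler
        words joining into a term) or one extending beyond a planted span
        from its start (e.g. location + injury fusing into a compound) —
        invalidates the sentence.  The check uses only the lexicon's surface
        set, never the tagger, so gold spans stay independent of the
        implementation under test.
        """
        # Word-run tokens (hyphen/decimal compounds stay whole) so window
        # ends line up with matchable term boundaries even when punctuation
        # like the sentence-final period is glued to the last word.
        tokens = [(m.start(), m.end()) for m in re.finditer(r"\w+(?:[-.]\w+)*", text)]
        planted_end_at: dict[int, int] = {s: e for s, e, _ in triples}
        intervals = sorted(planted_end_at.items())

        def inside_planted(pos: int) -> bool:
            return any(s < pos < e for s, e in intervals)

        for i in range(len(tokens)):
            for j in range(i + 1, min(i + 1 + self._MAX_WINDOW, len(tokens) + 1)):
                s, e = tokens[i][0], tokens[j - 1][1]
                window = text[s:e].lower()
                normalized = " ".join(
                    "<num>" if _NUM_FULL.fullmatch(tok) else tok
                    for tok in window.split(" ")
                )
                if window not in self._surface_set and normalized not in self._pattern_set:
                    continue
                if planted_end_at.get(s) is not None and e <= planted_end_at[s]:
                    continue  # planted span itself, or a shorter losing alternative
                if inside_planted(s):
                    continue  # unreachable: scan never probes planted interiors
                return True
        return False

    def _build_sentence(self, category: str) -> tuple[str, list, Optional[InjuryStatus]]:
        for _ in range(64):
            plan = self._plan_mention(category)
            text, triples = self._assemble(plan)
            if not self._has_accidental_match(text, triples):
                return text, triples, self._gold_status(plan)
        raise GeneratorSpecError(
            f"could not assemble a collision-free sentence for {category!r}"
        )

    def _pad_sentence(self) -> tuple[str, list]:
        text = self._pick(_PAD_SENTENCES) + "."
        triples = [(len(text) - 1, len(text), self._end_line_term())]
        return text, triples

    # -- report and corpus --------------------------------------------------
    def generate_report(self, report_id: str, patient_id: str) -> GoldReport:
        spec = self.spec
        rng = self.rng
        mentioned = [c for c in DECODER_CATEGORIES if rng.random() < spec.prevalence.get(c, 0.0)]
        lo, hi = spec.sentences_per_report
        n_target = int(rng.integers(lo, hi + 1))

        sentence_payloads: list[tuple[str, list, Optional[tuple[str, InjuryStatus]]]] = []
        labels: dict[str, InjuryStatus] = {
            c: InjuryStatus.NOT_MENTIONED for c in DECODER_CATEGORIES
        }
        for cat in mentioned:
            text, triples, status = self._build_sentence(cat)
            sentence_payloads.append((text, triples, None))
            if status is not None:
                labels[cat] = InjuryStatus.merge(labels[cat], status)
        while len(sentence_payloads) < n_target:
            text, triples = self._pad_sentence()
            sentence_payloads.append((text, triples, None))
        order = rng.permutation(len(sentence_payloads))
        sentence_payloads = [sentence_payloads[i] for i in order]
        n_findings = int(rng.integers(1, len(sentence_payloads) + 1))

        parts: list[str] = []
        sentences: list[Sentence] = []
        gold_spans: list[EntitySpan] = []
        cursor = 0

        def emit_section(header: str, payloads, kind: str) -> None:
            nonlocal cursor
            if not payloads:
                return
            if parts:
                parts.append("\n")
                cursor += 1
            head = f"{header}: "
            parts.append(head)
            cursor += len(head)
            for k, (text, triples, _) in enumerate(payloads):
                if k > 0:
                    parts.append(" ")
                    cursor += 1
                start = cursor
                parts.append(text)
                cursor += len(text)
                idx = len(sentences)
                sentences.append(
                    Sentence(
                        report_id=report_id,
                        section_kind=kind,
                        index=idx,
                        start=start,
                        end=cursor,
                        text=text,
                    )
                )
                for s, e, term in triples:
                    gold_spans.append(
                        EntitySpan(
                            report_id=report_id,
                            sentence_index=idx,
                            start=s,
                            end=e,
                            surface=text[s:e],
                            entity=term.entity,
                            category=self.lexicon.category_of(term.entity),
                            chronic_marker=term.chronic_marker,
                            recent_past_marker=term.recent_past_marker,
                            extracranial_marker=term.extracranial_marker,
                        )
                    )

        emit_section("FINDINGS", sentence_payloads[:n_findings], "FINDINGS")
        emit_section("IMPRESSION", sentence_payloads[n_findings:], "IMPRESSION")

        report = RawReport(report_id=report_id, patient_id=patient_id, text="".join(parts))
        summary = ReportSummary(report_id=report_id, labels=labels)
        return GoldReport(report, sentences, gold_spans, summary)

    def generate_corpus(self) -> list[GoldReport]:
        width = max(4, len(str(max(self.spec.n_reports, 1))))
        return [
            self.generate_report(f"R{i:0{width}d}", f"P{i:0{width}d}")
            for i in range(self.spec.n_reports)
        ]


def generate_corpus(spec: GeneratorSpec, lexicon: Optional[Lexicon] = None) -> list[GoldReport]:
    """Generate a seeded synthetic corpus; same spec + seed, same bytes."""
    return CorpusGenerator(spec, lexicon).generate_corpus()


def corpus_stats(corpus: Sequence[GoldReport]) -> dict:
    """Exact tallies over a generated corpus."""
    spans_per_entity: Counter = Counter()
    labels_per_category: dict[str, Counter] = {c: Counter() for c in DECODER_CATEGORIES}
    n_sentences = 0
    for gr in corpus:
        n_sentences += len(gr.sentences)
        for s in gr.gold_spans:
            spans_per_entity[s.entity] += 1
        for c in DECODER_CATEGORIES:
            labels_per_category[c][gr.gold_summary.labels[c].name] += 1
    return {
        "n_reports": len(corpus),
        "n_sentences": n_sentences,
        "spans_per_entity": dict(spans_per_entity),
        "labels_per_category": {c: dict(v) for c, v in labels_per_category.items()},
    }


def write_gold_corpus(corpus: Sequence[GoldReport], out_dir: str | Path) -> dict[str, Path]:
    """Emit corpus JSONL plus gold spans (long-format CSV) and gold labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out_dir / "corpus.jsonl",
        "gold_spans": out_dir / "gold_spans.csv",
        "gold_labels": out_dir / "gold_labels.csv",
    }
    write_corpus([gr.report for gr in corpus], paths["corpus"])
    all_spans = [s for gr in corpus for s in gr.gold_spans]
    to_long(all_spans).to_csv(paths["gold_spans"], index=False)
    labels_frame([gr.gold_summary for gr in corpus]).to_csv(
        paths["gold_labels"], index=False
    )
    return paths
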