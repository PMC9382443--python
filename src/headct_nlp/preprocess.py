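"""Report preprocessing: de-identification, section detection, sentence split.

All coordinates are 0-based, half-open character offsets into the text the
operation received, so downstream spans can always be traced back to a slice
of the de-identified report.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml


@dataclass(frozen=True)
class RawReport:
    report_id: str
    patient_id: str
    text: str


@dataclass(frozen=True)
class Redaction:
    """One removed identifier: its class and original-text offsets."""

    klass: str
    start: int
    end: int
    original: str


@dataclass(frozen=True)
class DeidRule:
    klass: str
    pattern: str
    replacement: str


@dataclass(frozen=True)
class Section:
    """A contiguous stretch of the report.

    ``start``/``end`` cover the full slice including any header so the
    returned sections tile the whole text; ``content_start`` skips past the
    header (equal to ``start`` for OTHER sections).
    """

    kind: str  # FINDINGS | IMPRESSION | OTHER
    start: int
    end: int
    content_start: int


@dataclass(frozen=True)
class Sentence:
    report_id: str
    section_kind: str
    index: int
    start: int
    end: int
    text: str


class DeidConfigError(ValueError):
    """A de-identification pattern failed to compile."""


# --------------------------------------------------------------------------
# De-identification
# --------------------------------------------------------------------------

#: Packaged default rules.  Order matters: earlier rules claim text first.
#: These mirror common PHI classes (names, record numbers, dates, phones,
#: care locations); they are a configurable starting point, not a certified
#: de-identification guarantee.
DEFAULT_DEID_RULES: tuple[DeidRule, ...] = (
    DeidRule(
        "NAME",
        r"(?:(?<=\bDr\.\s)|(?<=\bMr\.\s)|(?<=\bMs\.\s)|(?<=\bMrs\.\s)"
        r"|(?<=\bPatient\s)|(?<=\bPatient:\s))"
        r"[A-Z][a-z]+(?:\s[A-Z][a-z]+)*",
        "[REDACTED:NAME]",
    ),
    DeidRule(
        "DATE",
        r"\b(?:\d{1,2}[/-]\d{1,2}[/-]\d{2,4}"
        r"|(?:January|February|March|April|May|June|July|August|September"
        r"|October|November|December)\s\d{1,2},?\s\d{4})\b",
        "[REDACTED:DATE]",
    ),
    DeidRule("PHONE", r"\b\d{3}[-.]\d{3}[-.]\d{4}\b", "[REDACTED:PHONE]"),
    DeidRule("ID", r"\b\d{6,10}\b", "[REDACTED:ID]"),
    DeidRule(
        "LOCATION",
        r"\b[A-Z][A-Za-z]*\s(?:Hospital|Medical Center|Clinic)\b",
        "[REDACTED:LOCATION]",
    ),
)


def load_deid_rules(path: str | Path) -> tuple[DeidRule, ...]:
    """Read an ordered rule list from YAML: ``[{class, pattern, replacement}]``."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    rules = tuple(
        DeidRule(r["class"], r["pattern"], r.get("replacement", f"[REDACTED:{r['class']}]"))
        for r in doc
    )
    _compile_rules(rules)  # fail fast on bad patterns
    return rules


def _compile_rules(rules: Sequence[DeidRule]) -> list[tuple[DeidRule, re.Pattern]]:
    compiled = []
    for rule in rules:
        try:
            compiled.append((rule, re.compile(rule.pattern)))
        except re.error as exc:
            raise DeidConfigError(
                f"deid rule {rule.klass!r}: invalid pattern {rule.pattern!r}: {exc}"
            ) from exc
    return compiled


def deidentify(
    text: str, patterns: Sequence[DeidRule] = DEFAULT_DEID_RULES
) -> tuple[str, list[Redaction]]:
    """Replace identifier matches with ``[REDACTED:<class>]`` placeholders.

    Rules are applied in order against the *original* text; a later rule
    cannot claim characters already claimed by an earlier one.  Unmatched
    text is preserved byte-identically, and redaction records report the
    original offsets and surface of each removal.
    """
    compiled = _compile_rules(patterns)
    claimed: list[tuple[int, int, DeidRule]] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s < ce and cs < e for cs, ce, _ in claimed)

    for rule, pat in compiled:
        for m in pat.finditer(text):
            if m.start() == m.end():
                continue
            if not overlaps(m.start(), m.end()):
                claimed.append((m.start(), m.end(), rule))
    claimed.sort(key=lambda c: c[0])

    out: list[str] = []
    redactions: list[Redaction] = []
    cursor = 0
    for s, e, rule in claimed:
        out.append(text[cursor:s])
        out.append(rule.replacement)
        redactions.append(Redaction(rule.klass, s, e, text[s:e]))
        cursor = e
    out.append(text[cursor:])
    return "".join(out), redactions


# --------------------------------------------------------------------------
# Section segmentation
# --------------------------------------------------------------------------

#: Header synonym table; configurable because header vocabulary varies by
#: institution.  INTERPRETATION and CONCLUSION are impression synonyms.
DEFAULT_SECTION_SYNONYMS: dict[str, str] = {
    "FINDINGS": "FINDINGS",
    "FINDING": "FINDINGS",
    "IMPRESSION": "IMPRESSION",
    "IMPRESSIONS": "IMPRESSION",
    "INTERPRETATION": "IMPRESSION",
    "CONCLUSION": "IMPRESSION",
    "CONCLUSIONS": "IMPRESSION",
}


def segment_sections(
    text: str, synonyms: Optional[dict[str, str]] = None
) -> list[Section]:
    """Split a report at section headers like ``FINDINGS:``.

    Returns sections that tile the text completely and in order.  Text before
    the first recognized header becomes one OTHER section; a report with no
    headers is a single OTHER section.
    """
    if synonyms is None:
        synonyms = DEFAULT_SECTION_SYNONYMS
    if not text:
        return []
    names = "|".join(sorted(synonyms, key=len, reverse=True))
    header_re = re.compile(rf"(?:(?<=\s)|^)({names})\s*:", re.IGNORECASE)
    headers = [
        (m.start(), m.end(), synonyms[m.group(1).upper()])
        for m in header_re.finditer(text)
    ]
    sections: list[Section] = []
    if not headers:
        return [Section("OTHER", 0, len(text), 0)]
    if headers[0][0] > 0:
        sections.append(Section("OTHER", 0, headers[0][0], 0))
    for i, (h_start, h_end, kind) in enumerate(headers):
        end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        content_start = h_end
        while content_start < end and text[content_start] in " \t\n":
            content_start += 1
        sections.append(Section(kind, h_start, end, content_start))
    return sections


# --------------------------------------------------------------------------
# Sentence splitting
# --------------------------------------------------------------------------

#: Period-terminated tokens that never end a sentence.
PROTECTED_ABBREVIATIONS = frozenset(
    {"vs.", "r/o.", "dr.", "mr.", "ms.", "mrs.", "cm.", "mm.", "e.g.", "i.e.",
     "approx.", "no."}
)

_TERMINATOR = re.compile(r"[.;\n]")
_ENUMERATOR = re.compile(r"(?:^|\n)\s*\d{1,2}\.$")


def _is_split_point(text: str, i: int) -> bool:
    """Decide whether the terminator character at ``i`` ends a sentence."""
    ch = text[i]
    if ch in ";\n":
        return True
    # Decimal guard: "1.5 cm" keeps its period.
    if i > 0 and text[i - 1].isdigit() and i + 1 < len(text) and text[i + 1].isdigit():
        return False
    # List enumerator guard: "1." at the start of a line.
    line_start = text.rfind("\n", 0, i) + 1
    if _ENUMERATOR.search(text[max(0, line_start - 1): i + 1]):
        return False
    # Protected abbreviations ("vs.", "cm.").
    tok_start = i
    while tok_start > 0 and not text[tok_start - 1].isspace():
        tok_start -= 1
    if text[tok_start: i + 1].lower() in PROTECTED_ABBREVIATIONS:
        return False
    return True


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence offset pairs (0-based, half-open).

    Sentences end at terminal periods, semicolons, or newlines; the
    terminator character stays inside its sentence.  Leading/trailing
    whitespace is trimmed from each sentence; empty stretches yield no
    sentence.  Offsets are relative to ``text``.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _TERMINATOR.finditer(text):
        i = m.start()
        if not _is_split_point(text, i):
            continue
        end = i if text[i] == "\n" else i + 1
        s, e = _trim(text, start, end)
        if s < e:
            spans.append((s, e))
        start = i + 1
    s, e = _trim(text, start, len(text))
    if s < e:
        spans.append((s, e))
    return spans


def _trim(text: str, s: int, e: int) -> tuple[int, int]:
    while s < e and text[s].isspace():
        s += 1
    while e > s and text[e - 1].isspace():
        e -= 1
    return s, e


def sentences_of_report(
    report: RawReport,
    sections: Optional[Sequence[Section]] = None,
    synonyms: Optional[dict[str, str]] = None,
) -> list[Sentence]:
    """Section a report and split each section into offset-faithful sentences.

    Sentence offsets are into ``report.text``; ``index`` is the sentence
    ordinal within the whole report.
    """
    if sections is None:
        sections = segment_sections(report.text, synonyms=synonyms)
    sentences: list[Sentence] = []
    idx = 0
    for sec in sections:
        body = report.text[sec.content_start: sec.end]
        for s, e in split_sentences(body):
            a, b = sec.content_start + s, sec.content_start + e
            sentences.append(
                Sentence(
                    report_id=report.report_id,
                    section_kind=sec.kind,
                    index=idx,
                    start=a,
                    end=b,
                    text=report.text[a:b],
                )
            )
            idx += 1
    return sentences


# --------------------------------------------------------------------------
# Corpus readers
# --------------------------------------------------------------------------

def read_corpus(path: str | Path) -> list[RawReport]:
    """Read reports from JSONL/CSV (report_id, patient_id, text) or a
    directory of ``.txt`` files (file stem = report_id = patient_id)."""
    path = Path(path)
    if path.is_dir():
        reports = [
            RawReport(p.stem, p.stem, p.read_text(encoding="utf-8"))
            for p in sorted(path.glob("*.txt"))
        ]
    elif path.suffix == ".jsonl":
        reports = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    reports.append(
                        RawReport(str(rec["report_id"]), str(rec["patient_id"]), rec["text"])
                    )
    elif path.suffix == ".csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reports = [
                RawReport(str(r["report_id"]), str(r["patient_id"]), r["text"])
                for r in csv.DictReader(fh)
            ]
    else:
        raise ValueError(f"unsupported corpus path: {path}")
    seen: set[str] = set()
    for r in reports:
        if r.report_id in seen:
            raise ValueError(f"duplicate report_id {r.report_id!r} in corpus")
        seen.add(r.report_id)
    return reports


def write_corpus(reports: Iterable[RawReport], path: str | Path) -> None:
    """Write reports as JSONL with keys report_id, patient_id, text."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {"report_id": r.report_id, "patient_id": r.patient_id, "text": r.text}
                )
                + "\n"
            )
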