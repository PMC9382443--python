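"""Structured entity dictionary driving tagging and decoding.

The dictionary maps surface *terms* (lowercase strings, possibly multi-word,
possibly containing the numeric placeholder ``<num>``) to *entities*, and each
entity to one of five categories: injuries, magnitude, location, time, and
other.  "Other" entities carry a functional subrole — negation, uncertainty,
or end-line (sentence-terminating punctuation).  Injury entities may map to
one of the 13 decoder categories used for report-level labelling.

Terms carry three boolean markers consumed by the decoder:

``chronic_marker``
    the term denotes chronic / longstanding disease (e.g. "atrophy",
    "small vessel ischemic disease", the time term "chronic"); such mentions
    are ignored at decode time.
``recent_past_marker``
    the term denotes an injury present in the recent past (e.g. "evolving",
    "stable"); such mentions are labelled positive even in a chronic context.
``extracranial_marker``
    a location outside the skull (scalp, orbit, ...); injuries in such a
    context are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

CATEGORIES = ("INJURY", "MAGNITUDE", "LOCATION", "TIME", "OTHER")
SUBROLES = ("NEGATION", "UNCERTAINTY", "END_LINE")

#: The 13 report-level injury categories the decoder labels, in canonical order.
DECODER_CATEGORIES = (
    "hemorrhage",
    "stroke",
    "hydrocephalus",
    "surgical_intervention",
    "herniation",
    "mass_effect",
    "midline_shift",
    "edema",
    "fluid",
    "lesion",
    "pneumocephalus",
    "vascular_malformation",
    "density",
)

#: Density mentions are decoded into the single "density" category; the
#: subtype (high / low / mixed / undifferentiated) is kept as a property.
DENSITY_SUBTYPES = ("high", "low", "mixed", "undifferentiated")

#: Placeholder token in pattern-typed magnitude terms ("<num> mm").
NUM_TOKEN = "<num>"

_WS = re.compile(r"\s+")

_TSV_COLUMNS = [
    "surface",
    "entity",
    "category",
    "subrole",
    "decoder_group",
    "chronic_marker",
    "recent_past_marker",
    "extracranial_marker",
]


class LexiconError(ValueError):
    """Base class for lexicon loading problems."""


class LexiconFormatError(LexiconError):
    """The file could not be parsed as a lexicon."""


class LexiconValidationError(LexiconError):
    """The file parsed but violates a lexicon invariant."""


def normalize_surface(surface: str) -> str:
    """Lowercase and collapse internal whitespace to single spaces."""
    return _WS.sub(" ", surface.strip()).lower()


@dataclass(frozen=True)
class EntityDef:
    """An entity: a named semantic type within one of the five categories."""

    name: str
    category: str
    subrole: Optional[str] = None
    decoder_group: Optional[str] = None


@dataclass(frozen=True)
class TermEntry:
    """A surface string mapped to an entity, with decoder-relevant markers."""

    surface: str
    entity: str
    chronic_marker: bool = False
    recent_past_marker: bool = False
    extracranial_marker: bool = False

    @property
    def is_pattern(self) -> bool:
        """True for pattern-typed terms containing the numeric placeholder."""
        return NUM_TOKEN in self.surface


@dataclass
class Lexicon:
    """A validated set of entities and terms."""

    entities: tuple[EntityDef, ...]
    terms: tuple[TermEntry, ...]
    version: str = "0"
    _by_name: dict[str, EntityDef] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._by_name = {e.name: e for e in self.entities}

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def entity(self, name: str) -> EntityDef:
        return self._by_name[name]

    def has_entity(self, name: str) -> bool:
        return name in self._by_name

    def category_of(self, entity_name: str) -> str:
        return self._by_name[entity_name].category

    def terms_in_category(self, category: str) -> list[TermEntry]:
        return [t for t in self.terms if self.category_of(t.entity) == category]

    def entities_in_category(self, category: str) -> list[EntityDef]:
        return [e for e in self.entities if e.category == category]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for e in self.entities:
            counts[e.category] += 1
        return counts


def validate_lexicon(lex: Lexicon) -> list[str]:
    """Check every lexicon invariant; return human-readable violations.

    Reports, never raises: an empty list means the lexicon is valid.
    """
    violations: list[str] = []
    seen_names: set[str] = set()
    for e in lex.entities:
        if e.name in seen_names:
            violations.append(f"duplicate entity name: {e.name!r}")
        seen_names.add(e.name)
        if e.category not in CATEGORIES:
            violations.append(f"entity {e.name!r}: unknown category {e.category!r}")
        if e.category == "OTHER":
            if e.subrole not in SUBROLES:
                violations.append(
                    f"entity {e.name!r}: OTHER entity must have subrole in {SUBROLES}"
                )
        elif e.subrole is not None:
            violations.append(
                f"entity {e.name!r}: subrole only allowed for OTHER entities"
            )
        if e.decoder_group is not None:
            if e.category != "INJURY":
                violations.append(
                    f"entity {e.name!r}: decoder_group only allowed for INJURY entities"
                )
            if e.decoder_group not in DECODER_CATEGORIES:
                violations.append(
                    f"entity {e.name!r}: unknown decoder_group {e.decoder_group!r}"
                )
    seen_pairs: set[tuple[str, str]] = set()
    for t in lex.terms:
        if not t.surface or t.surface != t.surface.strip():
            violations.append(
                f"term {t.surface!r} ({t.entity}): surface empty or not stripped"
            )
        if t.surface != normalize_surface(t.surface):
            violations.append(
                f"term {t.surface!r} ({t.entity}): surface not normalized"
            )
        if (t.surface, t.entity) in seen_pairs:
            violations.append(f"duplicate (surface, entity): ({t.surface!r}, {t.entity!r})")
        seen_pairs.add((t.surface, t.entity))
        if t.entity not in {e.name for e in lex.entities}:
            violations.append(f"term {t.surface!r}: unknown entity {t.entity!r}")
        if t.chronic_marker and t.recent_past_marker:
            violations.append(
                f"term {t.surface!r} ({t.entity}): chronic_marker and "
                "recent_past_marker are mutually exclusive"
            )
    return violations


def _parse_bool(value: str, line_no: int) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise LexiconFormatError(f"line {line_no}: boolean field must be 0 or 1, got {value!r}")


def _records_to_lexicon(
    entity_records: Iterable[dict], term_records: Iterable[dict], version: str
) -> Lexicon:
    entities = tuple(
        EntityDef(
            name=r["name"],
            category=r["category"],
            subrole=r.get("subrole") or None,
            decoder_group=r.get("decoder_group") or None,
        )
        for r in entity_records
    )
    terms = tuple(
        TermEntry(
            surface=normalize_surface(r["surface"]),
            entity=r["entity"],
            chronic_marker=bool(r.get("chronic_marker", False)),
            recent_past_marker=bool(r.get("recent_past_marker", False)),
            extracranial_marker=bool(r.get("extracranial_marker", False)),
        )
        for r in term_records
    )
    lex = Lexicon(entities=entities, terms=terms, version=version)
    violations = validate_lexicon(lex)
    if violations:
        raise LexiconValidationError(
            "invalid lexicon:\n" + "\n".join(f"  - {v}" for v in violations)
        )
    return lex


def _load_tabular(path: Path) -> Lexicon:
    # One row per term; entity attributes (category, subrole, decoder_group)
    # are repeated on each row and must agree across rows of one entity.
    entity_attrs: dict[str, dict] = {}
    term_records: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if header != _TSV_COLUMNS:
            raise LexiconFormatError(
                f"line 1: expected header {_TSV_COLUMNS}, got {header}"
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise LexiconFormatError(
                    f"line {line_no}: expected {len(_TSV_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(_TSV_COLUMNS, fields))
            attrs = {
                "name": row["entity"],
                "category": row["category"],
                "subrole": row["subrole"] or None,
                "decoder_group": row["decoder_group"] or None,
            }
            prev = entity_attrs.setdefault(row["entity"], attrs)
            if prev != attrs:
                raise LexiconFormatError(
                    f"line {line_no}: entity {row['entity']!r} redefined with "
                    "conflicting attributes"
                )
            term_records.append(
                {
                    "surface": row["surface"],
                    "entity": row["entity"],
                    "chronic_marker": _parse_bool(row["chronic_marker"], line_no),
                    "recent_past_marker": _parse_bool(row["recent_past_marker"], line_no),
                    "extracranial_marker": _parse_bool(row["extracranial_marker"], line_no),
                }
            )
    return _records_to_lexicon(entity_attrs.values(), term_records, version=path.stem)


def _load_structured(path: Path) -> Lexicon:
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise LexiconFormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict) or "entities" not in doc or "terms" not in doc:
        raise LexiconFormatError(
            f"{path}: structured lexicon needs top-level 'entities' and 'terms' lists"
        )
    return _records_to_lexicon(
        doc["entities"], doc["terms"], version=str(doc.get("version", path.stem))
    )


def load_lexicon(path: str | Path, format: str = "tabular") -> Lexicon:
    """Load and validate a lexicon file.

    Parameters
    ----------
    path
        Path to a lexicon file.
    format
        ``"tabular"`` — UTF-8 TSV with columns surface, entity, category,
        subrole, decoder_group, chronic_marker, recent_past_marker,
        extracranial_marker (booleans serialized 0/1); or ``"structured-text"``
        — a YAML document with ``entities`` and ``terms`` lists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _load_tabular(path)
    if format == "structured-text":
        return _load_structured(path)
    raise ValueError(f"unknown lexicon format {format!r}")


def write_lexicon(lex: Lexicon, path: str | Path, format: str = "tabular") -> None:
    """Serialize a lexicon; round-trips through :func:`load_lexicon`."""
    path = Path(path)
    by_name = {e.name: e for e in lex.entities}
    if format == "tabular":
        lines = ["\t".join(_TSV_COLUMNS)]
        for t in lex.terms:
            e = by_name[t.entity]
            lines.append(
                "\t".join(
                    [
                        t.surface,
                        t.entity,
                        e.category,
                        e.subrole or "",
                        e.decoder_group or "",
                        str(int(t.chronic_marker)),
                        str(int(t.recent_past_marker)),
                        str(int(t.extracranial_marker)),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "structured-text":
        doc = {
            "version": lex.version,
            "entities": [
                {
                    "name": e.name,
                    "category": e.category,
                    "subrole": e.subrole,
                    "decoder_group": e.decoder_group,
                }
                for e in lex.entities
            ],
            "terms": [
                {
                    "surface": t.surface,
                    "entity": t.entity,
                    "chronic_marker": t.chronic_marker,
                    "recent_past_marker": t.recent_past_marker,
                    "extracranial_marker": t.extracranial_marker,
                }
                for t in lex.terms
            ],
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    else:
        raise ValueError(f"unknown lexicon format {format!r}")


_DEFAULT_CACHE: Optional[Lexicon] = None


def default_lexicon() -> Lexicon:
    """The packaged default head-CT dictionary (64 entities, 469 terms).

    Note: the tabular load path caches the result; callers must not mutate it.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        ref = resources.files("headct_nlp").joinpath("data/default_lexicon.tsv")
        with resources.as_file(ref) as p:
            lex = load_lexicon(p, format="tabular")
        _DEFAULT_CACHE = replace(lex, version="default-1.0")
    return _DEFAULT_CACHE
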