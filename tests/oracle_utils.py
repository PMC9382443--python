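"""Brute-force tagging oracle, independent of the package's matcher.

Enumerates every candidate (start, end, term) by direct slice comparison,
then selects the leftmost-longest non-overlapping tiling by explicit
greedy construction.  Shares no code with headct_nlp.tagger.
"""

from __future__ import annotations

import re

from headct_nlp.lexicon import EntityDef, Lexicon, TermEntry

_NUM = re.compile(r"\d+(?:\.\d+)?")


def _is_word_char(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def _slice_matches(slice_text: str, surface: str) -> bool:
    """Token-by-token comparison; '<num>' matches a number token."""
    got = slice_text.lower().split(" ")
    want = surface.split(" ")
    if len(got) != len(want):
        return False
    for g, w in zip(got, want):
        if w == "<num>":
            if not _NUM.fullmatch(g):
                return False
        elif g != w:
            return False
    return True


def candidate_spans(text: str, lex: Lexicon) -> list[tuple[int, int, TermEntry]]:
    """All boundary-respecting term occurrences, by exhaustive enumeration."""
    out = []
    n = len(text)
    for term in lex.terms:
        for start in range(n):
            for end in range(start + 1, n + 1):
                if not _slice_matches(text[start:end], term.surface):
                    continue
                first, last = text[start], text[end - 1]
                if _is_word_char(first) and start > 0 and _is_word_char(text[start - 1]):
                    continue
                if _is_word_char(last) and end < n and _is_word_char(text[end]):
                    continue
                out.append((start, end, term))
    return out


def oracle_tag(text: str, lex: Lexicon) -> list[tuple[int, int, str]]:
    """Leftmost-longest non-overlapping tiling over the candidate set.

    Returns (start, end, entity) triples.  Assumes surfaces are unambiguous
    (no surface mapped to two entities), which every caller guarantees.
    """
    candidates = candidate_spans(text, lex)
    chosen: list[tuple[int, int, str]] = []
    cursor = 0
    while True:
        viable = [c for c in candidates if c[0] >= cursor]
        if not viable:
            break
        leftmost = min(c[0] for c in viable)
        at_leftmost = [c for c in viable if c[0] == leftmost]
        start, end, term = max(at_leftmost, key=lambda c: c[1])
        chosen.append((start, end, term.entity))
        cursor = end
    return chosen


# ---------------------------------------------------------------------------
# Random (sentence, mini-lexicon) instance generation
# ---------------------------------------------------------------------------

_WORDS = ["ab", "abc", "ba", "cab", "bc", "a", "cc", "abab", "b", "ca"]


def random_instance(rng) -> tuple[str, Lexicon]:
    """A short sentence over a tiny alphabet plus a mini-lexicon of 3-15
    unique surfaces (some multi-word, occasionally a numeric pattern), built
    to stress prefix/suffix overlap between terms."""
    n_terms = int(rng.integers(3, 16))
    surfaces: set[str] = set()
    while len(surfaces) < n_terms:
        k = int(rng.integers(1, 4))
        words = [_WORDS[int(rng.integers(0, len(_WORDS)))] for _ in range(k)]
        if rng.random() < 0.1:
            words[int(rng.integers(0, k))] = "<num>"
        surfaces.add(" ".join(words))
    entities = []
    terms = []
    for i, s in enumerate(sorted(surfaces)):
        name = f"e{i}"
        entities.append(EntityDef(name=name, category="LOCATION"))
        terms.append(TermEntry(surface=s, entity=name))
    lex = Lexicon(entities=tuple(entities), terms=tuple(terms), version="mini")

    n_tokens = int(rng.integers(1, 13))
    tokens = []
    for _ in range(n_tokens):
        r = rng.random()
        if r < 0.7:
            tokens.append(_WORDS[int(rng.integers(0, len(_WORDS)))])
        elif r < 0.85:
            tokens.append(str(int(rng.integers(0, 100))))
        else:
            tokens.append("zz")  # never in any lexicon
    text = " ".join(tokens)
    if rng.random() < 0.3:
        text += "."
    return text, lex
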