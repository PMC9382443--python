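import pytest

from headct_nlp.lexicon import EntityDef, Lexicon, TermEntry, default_lexicon
from headct_nlp.preprocess import Sentence
from headct_nlp.tagger import DictionaryTagger


@pytest.fixture(scope="session")
def lex() -> Lexicon:
    return default_lexicon()


@pytest.fixture(scope="session")
def tagger(lex) -> DictionaryTagger:
    return DictionaryTagger(lex)


@pytest.fixture
def make_sentence():
    def _make(text: str, index: int = 0, report_id: str = "r1",
              section_kind: str = "FINDINGS") -> Sentence:
        return Sentence(
            report_id=report_id,
            section_kind=section_kind,
            index=index,
            start=0,
            end=len(text),
            text=text,
        )

    return _make


@pytest.fixture
def mini_lexicon():
    """Builder for tiny ad-hoc lexicons: surfaces -> one entity each."""

    def _build(surfaces: list[str], category: str = "LOCATION") -> Lexicon:
        entities = tuple(
            EntityDef(name=f"e{i}", category=category) for i in range(len(surfaces))
        )
        terms = tuple(
            TermEntry(surface=s, entity=f"e{i}") for i, s in enumerate(surfaces)
        )
        return Lexicon(entities=entities, terms=terms, version="mini")

    return _build
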