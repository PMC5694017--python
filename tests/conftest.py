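import pytest

from girem.corpus_io import AbstractDoc, GeneLexicon, GoAnnotationTable
from girem.extraction import RuleLexicon, Sentence, tokenize


@pytest.fixture(scope="session")
def rules() -> RuleLexicon:
    return RuleLexicon.load()


@pytest.fixture(scope="session")
def toy_lexicon() -> GeneLexicon:
    return GeneLexicon(
        entries={
            "GA": "geneA",
            "GB": "geneB",
            "GC": "geneC",
            "G1": "TP53",
            "G2": "BRCA1",
        }
    )


@pytest.fixture(scope="session")
def toy_go_table() -> GoAnnotationTable:
    return GoAnnotationTable(
        records={
            "GA": frozenset({("GO:0006915", "apoptotic process")}),
            "GB": frozenset({("GO:0006915", "apoptotic process"),
                             ("GO:0007049", "cell cycle")}),
            "G1": frozenset({("GO:0006915", "apoptotic process")}),
            "G2": frozenset({("GO:0006281", "DNA repair")}),
        }
    )


def make_sentence(text: str, doc_id: str = "doc1", sent_index: int = 0) -> Sentence:
    return Sentence(
        doc_id=doc_id, sent_index=sent_index, text=text, token_spans=tokenize(text)
    )


def make_doc(text: str, doc_id: str = "doc1") -> AbstractDoc:
    return AbstractDoc(doc_id=doc_id, text=text)


@pytest.fixture(scope="session")
def sentence_factory():
    return make_sentence


@pytest.fixture(scope="session")
def doc_factory():
    return make_doc
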