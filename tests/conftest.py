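import pytest

from vonorm.vocabulary import Concept, VocabularyIndex


def make_vocab(entries: dict[str, tuple[str, list[str], list[str]]]) -> VocabularyIndex:
    """Build a vocabulary from {id: (preferred, synonyms, parents)}."""
    index = VocabularyIndex()
    for cid, (label, synonyms, parents) in entries.items():
        index.add(Concept(cid, label, tuple(synonyms), tuple(parents)))
    return index


@pytest.fixture
def toy_vocab() -> VocabularyIndex:
    """Small vaccine vocabulary with synonyms, ambiguity and a 3-level is-a chain."""
    return make_vocab({
        "VO:1": ("vaccine", [], []),
        "VO:2": ("conjugate vaccine", [], ["VO:1"]),
        "VO:3": ("meningococcal conjugate vaccine", ["MCV4"], ["VO:2"]),
        "VO:4": ("Menveo", ["MenACWY-CRM"], ["VO:3"]),
        "VO:5": ("influenza vaccine", ["flu vaccine"], ["VO:1"]),
        "VO:6": ("FluMist", ["flumist quadrivalent"], ["VO:5"]),
        "VO:7": ("AIDSVAX B/E", [], ["VO:1"]),
    })


@pytest.fixture
def toy_graph(toy_vocab):
    return toy_vocab.graph()
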