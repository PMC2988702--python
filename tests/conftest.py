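import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from litdisc.corpus import Corpus, DocumentRecord, LexiconEntry, TargetLexicon


def make_doc(doc_id, text="", journal="J1", volume="V1", issue="I1",
             mesh=(), **units):
    text_units = {"abstract": text} if text or not units else {}
    text_units.update(units)
    return DocumentRecord(
        doc_id=doc_id, journal=journal, volume=volume, issue=issue,
        mesh_terms=frozenset(mesh), text_units=text_units,
    )


@pytest.fixture
def ros_lexicon():
    """Small lexicon mirroring a curated gene dictionary's top rows."""
    return TargetLexicon(entries=[
        LexiconEntry("INS", "insulin", ("INS", "insulin", "proinsulin"),
                     (True, False, False)),
        LexiconEntry("CAT", "catalase", ("CAT", "catalase"), (True, False)),
        LexiconEntry("SOD1", "superoxide dismutase 1", ("SOD1", "Sod1"),
                     (True, True)),
        LexiconEntry("TNF", "tumor necrosis factor", ("TNF", "TNF-alpha"),
                     (True, True)),
    ])


@pytest.fixture
def toy_corpus(ros_lexicon):
    return Corpus(documents=[
        make_doc("d1", "proinsulin levels rose after treatment"),
        make_doc("d2", "insulin and catalase activity in tissue"),
        make_doc("d3", "no gene names here at all"),
    ], label="toy")
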