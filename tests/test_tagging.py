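"""Dictionary tagger, occurrence matrix, and gold-standard evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litdisc.corpus import (
    Corpus,
    CorpusValidationError,
    GoldStandard,
    LexiconEntry,
    TargetLexicon,
)
from litdisc.tagging import (
    CompiledLexicon,
    DocumentTargetMatrix,
    evaluate_against_gold,
    f_measure,
    merge_curated_targets,
    read_matrix,
    tag_corpus,
    tag_document,
    tag_text,
    write_matrix,
)
from conftest import make_doc
from oracles import naive_tag_text


class TestTagDocument:
    def test_synonym_hits_canonical_symbol(self, ros_lexicon):
        doc = make_doc("d1", "proinsulin levels rose")
        assert tag_document(doc, ros_lexicon) == {"INS"}

    def test_two_targets_in_one_sentence(self, ros_lexicon):
        doc = make_doc("d1", "insulin and catalase")
        hits = tag_document(doc, ros_lexicon)
        assert hits == {"INS", "CAT"}
        compiled = CompiledLexicon(ros_lexicon)
        assert tag_text("insulin and catalase", compiled) == naive_tag_text(
            "insulin and catalase", ros_lexicon
        )

    def test_empty_text(self, ros_lexicon):
        assert tag_document(make_doc("d1", ""), ros_lexicon) == set()

    def test_word_boundaries(self, ros_lexicon):
        # CAT must not fire inside CATALOG or concatenate; hyphen is a boundary
        assert tag_document(make_doc("d1", "the CATALOG of concatenated data"),
                            ros_lexicon) == set()
        assert tag_document(make_doc("d1", "effects of TNF-alpha signalling"),
                            ros_lexicon) == {"TNF"}
        assert tag_document(make_doc("d1", "CAT-deficient mice"),
                            ros_lexicon) == {"CAT"}

    def test_case_sensitivity_per_string(self, ros_lexicon):
        # 'CAT' is a case-sensitive symbol; 'catalase' matches any case
        assert tag_document(make_doc("d1", "the cat sat"), ros_lexicon) == set()
        assert tag_document(make_doc("d1", "Catalase activity"), ros_lexicon) == {"CAT"}

    def test_unknown_scope_unit(self, ros_lexicon):
        with pytest.raises(CorpusValidationError):
            tag_document(make_doc("d1", "x"), ros_lexicon, scope={"body"})
        with pytest.raises(CorpusValidationError):
            tag_document(make_doc("d1", "x"), ros_lexicon, scope=set())

    def test_blacklist_always(self, ros_lexicon):
        lex = TargetLexicon(entries=ros_lexicon.entries,
                            blacklist={("CAT", "*")})
        assert tag_document(make_doc("d1", "CAT and catalase"), lex) == {"CAT"}
        lex2 = TargetLexicon(entries=ros_lexicon.entries,
                             blacklist={("CAT", "*"), ("catalase", "")})
        assert tag_document(make_doc("d1", "CAT and catalase"), lex2) == set()

    def test_blacklist_contextual(self, ros_lexicon):
        lex = TargetLexicon(entries=ros_lexicon.entries,
                            blacklist={("CAT", "scanner")})
        assert tag_document(make_doc("d1", "CAT scanner images"), lex) == set()
        assert tag_document(make_doc("d1", "CAT activity assay"), lex) == {"CAT"}

    def test_longest_match_wins_overlap(self):
        # 'serum albumin' should suppress the contained 'albumin' of a rival
        lex = TargetLexicon(entries=[
            LexiconEntry("ALB", "albumin", ("albumin",), (False,)),
            LexiconEntry("SA", "serum albumin product", ("serum albumin",), (False,)),
        ])
        assert tag_text("raised serum albumin found", CompiledLexicon(lex)) == {"SA"}
        assert naive_tag_text("raised serum albumin found", lex) == {"SA"}

    def test_collision_reported(self):
        lex = TargetLexicon(entries=[
            LexiconEntry("NOS1", "nitric oxide synthase 1", ("NOS",), (True,)),
            LexiconEntry("NOS2", "nitric oxide synthase 2", ("NOS",), (True,)),
        ])
        compiled = CompiledLexicon(lex)
        assert compiled.collisions == {"nos": ["NOS1", "NOS2"]}
        # without disambiguation both owners are attributed
        assert tag_text("induction of NOS", compiled) == {"NOS1", "NOS2"}


@st.composite
def lexicon_and_text(draw):
    alphabet = "ab xy-"
    n_entries = draw(st.integers(1, 4))
    entries = []
    for i in range(n_entries):
        n_strings = draw(st.integers(1, 3))
        strings = tuple(
            draw(st.text("abxyAB", min_size=1, max_size=5).filter(str.strip))
            for _ in range(n_strings)
        )
        flags = tuple(draw(st.booleans()) for _ in strings)
        entries.append(LexiconEntry(f"T{i}", f"target {i}", strings, flags))
    text = draw(st.text(alphabet + alphabet.upper(), max_size=60))
    return TargetLexicon(entries=entries), text


class TestMatcherOracleEquivalence:
    @given(lexicon_and_text())
    @settings(max_examples=400, deadline=None)
    def test_agrees_with_naive_position_scan(self, case):
        lexicon, text = case
        assert tag_text(text, CompiledLexicon(lexicon)) == naive_tag_text(text, lexicon)

    def test_agrees_on_generated_documents(self):
        from litdisc.simulate import SyntheticConfig, generate_corpus, generate_lexicon

        config = SyntheticConfig(
            n_targets=20, universe_docs=60, foreground_docs=10, n_planted=3,
            network=None or SyntheticConfig().network, seed=5,
        )
        rng = np.random.default_rng(1)
        lexicon = generate_lexicon(config, rng)
        universe, _, _ = generate_corpus(config, lexicon, seed=7)
        compiled = CompiledLexicon(lexicon)
        for doc in list(universe)[:50]:
            text = doc.text(("title", "abstract", "fulltext"))
            assert tag_text(text, compiled) == naive_tag_text(text, lexicon)

    def test_adding_match_string_is_monotone(self, ros_lexicon):
        texts = ["proinsulin and XDH in plasma", "XOR activity", "nothing"]
        extended = TargetLexicon(entries=ros_lexicon.entries + [
            LexiconEntry("XDH", "xanthine dehydrogenase", ("XDH", "XOR"),
                         (True, True)),
        ])
        for text in texts:
            base = naive_tag_text(text, ros_lexicon)
            assert base <= tag_text(text, CompiledLexicon(extended))


class TestTagCorpus:
    def test_unmatched_targets_omitted(self, ros_lexicon):
        corpus = Corpus(documents=[
            make_doc("d1", "insulin everywhere"), make_doc("d2", "no hits"),
        ])
        matrix = tag_corpus(corpus, ros_lexicon)
        assert matrix.target_ids == ["INS"]
        assert matrix.doc_counts()["INS"] == 1
        assert matrix.doc_ids == ["d1", "d2"]

    def test_deterministic(self, toy_corpus, ros_lexicon):
        m1 = tag_corpus(toy_corpus, ros_lexicon)
        m2 = tag_corpus(toy_corpus, ros_lexicon)
        assert m1.doc_ids == m2.doc_ids and m1.target_ids == m2.target_ids
        assert np.array_equal(m1.occurrence, m2.occurrence)

    def test_recovers_generator_truth(self):
        from litdisc.simulate import SyntheticConfig, generate_corpus, generate_lexicon

        config = SyntheticConfig(n_targets=30, universe_docs=120,
                                 foreground_docs=20, n_planted=4, seed=3)
        lexicon = generate_lexicon(config, np.random.default_rng(11))
        universe, _, truth = generate_corpus(config, lexicon, seed=13)
        matrix = tag_corpus(universe, lexicon)
        for i, doc_id in enumerate(matrix.doc_ids):
            found = {t for t, v in zip(matrix.target_ids, matrix.occurrence[i]) if v}
            assert found == truth.mentions[doc_id]

    def test_scope_monotone(self):
        corpus = Corpus(documents=[
            make_doc("d1", abstract="insulin here", fulltext="catalase only deep"),
            make_doc("d2", abstract="nothing", fulltext="proinsulin detail"),
        ])
        lex = TargetLexicon(entries=[
            LexiconEntry("INS", "insulin", ("insulin", "proinsulin"), (False, False)),
            LexiconEntry("CAT", "catalase", ("catalase",), (False,)),
        ])
        narrow = tag_corpus(corpus, lex, scope={"title", "abstract"})
        wide = tag_corpus(corpus, lex, scope={"title", "abstract", "fulltext"})
        for i, d in enumerate(narrow.doc_ids):
            narrow_t = {t for t, v in zip(narrow.target_ids, narrow.occurrence[i]) if v}
            j = wide.doc_ids.index(d)
            wide_t = {t for t, v in zip(wide.target_ids, wide.occurrence[j]) if v}
            assert narrow_t <= wide_t

    def test_matrix_round_trip(self, toy_corpus, ros_lexicon, tmp_path):
        matrix = tag_corpus(toy_corpus, ros_lexicon)
        path = tmp_path / "m.tsv"
        write_matrix(matrix, path)
        back = read_matrix(path)
        assert back.doc_ids == matrix.doc_ids
        assert back.target_ids == matrix.target_ids
        assert np.array_equal(back.occurrence, matrix.occurrence)


class TestEvaluation:
    @staticmethod
    def _matrix_with_targets(targets):
        mentions = {"d1": set(targets)}
        return DocumentTargetMatrix.from_mentions(["d1"], mentions)

    def test_recall_85_of_90(self):
        gold_targets = [f"T{i:03d}" for i in range(90)]
        identified = gold_targets[:85] + [f"X{i}" for i in range(936)]
        matrix = self._matrix_with_targets(identified)
        gold = GoldStandard(pairs=frozenset(("dx", t) for t in gold_targets))
        metrics = evaluate_against_gold(matrix, gold, level="target_set")
        assert round(100 * metrics.recall) == 94
        assert metrics.true_positives == 85 and metrics.false_negatives == 5

    def test_perfect_agreement(self):
        matrix = self._matrix_with_targets(["A", "B", "C"])
        gold = GoldStandard(pairs=frozenset(("g", t) for t in "ABC"))
        m = evaluate_against_gold(matrix, gold, gold_exhaustive=True)
        assert m.recall == m.precision == m.f_measure == 1.0

    def test_f_measure_formula(self):
        # harmonic mean of the printed benchmark recall/precision
        assert f_measure(0.871, 0.713) == pytest.approx(0.784, abs=5e-4)
        assert f_measure(0.0, 0.0) == 0.0
        assert math.isnan(f_measure(0.5, float("nan")))

    def test_precision_undefined_without_exhaustive_gold(self):
        matrix = self._matrix_with_targets(["A", "B"])
        gold = GoldStandard(pairs=frozenset({("g", "A")}))
        m = evaluate_against_gold(matrix, gold)
        assert math.isnan(m.precision) and math.isnan(m.f_measure)

    def test_pair_level(self):
        matrix = DocumentTargetMatrix.from_mentions(
            ["d1", "d2"], {"d1": {"A", "B"}, "d2": {"A"}}
        )
        gold = GoldStandard(pairs=frozenset({("d1", "A"), ("d2", "B")}))
        m = evaluate_against_gold(matrix, gold, level="pair", gold_exhaustive=True)
        assert m.true_positives == 1 and m.false_negatives == 1 and m.false_positives == 2

    def test_empty_gold_rejected(self, toy_corpus, ros_lexicon):
        matrix = tag_corpus(toy_corpus, ros_lexicon)
        with pytest.raises(CorpusValidationError):
            evaluate_against_gold(matrix, GoldStandard(pairs=frozenset()))


class TestMergeCuratedTargets:
    def test_published_bookkeeping(self):
        identified = {f"I{i}" for i in range(1021)}
        overlap = set(list(identified)[:85])
        gold = overlap | {f"M{i}" for i in range(5)}
        merged, counts = merge_curated_targets(identified, gold)
        assert counts.n_identified == 1021
        assert counts.n_gold == 90
        assert counts.n_overlap == 85
        assert counts.n_merged == 1026
        assert len(merged) == 1026

    def test_subset_and_disjoint(self):
        merged, _ = merge_curated_targets({"A", "B"}, {"A"})
        assert merged == {"A", "B"}
        merged, counts = merge_curated_targets({"A", "B", "C"}, {"X", "Y"})
        assert counts.n_merged == 5 and counts.n_overlap == 0
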