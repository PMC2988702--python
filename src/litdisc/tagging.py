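"""Dictionary-based gene-mention tagging and tagger evaluation.

Each lexicon match string is compiled to a boundary-anchored pattern (a word
boundary is any transition between alphanumeric and non-alphanumeric text, so
hyphenated strings like ``TNF-alpha`` match literally).  All candidate
occurrences of all strings are collected, overlaps are resolved greedily —
longest match first, then leftmost, ties broken by lexicon order — and the
blacklist is applied after matching.  Occurrences are binarised per document:
a document either mentions a target or it does not, which is the unit of all
downstream frequency statistics.

Symbol collisions (one match string shared by several targets) are not
disambiguated; they attribute the mention to every owner and are reported in
a collision log for manual blacklisting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import (
    Corpus,
    CorpusValidationError,
    DocumentRecord,
    GoldStandard,
    TargetLexicon,
    TEXT_UNIT_NAMES,
)

_BOUNDARY_L = r"(?<![0-9A-Za-z])"


@dataclass(frozen=True)
class _CompiledString:
    target_id: str
    string: str
    lexicon_index: int
    pattern: re.Pattern


class CompiledLexicon:
    """Lexicon with per-string compiled patterns; reusable across documents."""

    def __init__(self, lexicon: TargetLexicon):
        self.lexicon = lexicon
        self.strings: list[_CompiledString] = []
        owners: dict[str, list[str]] = {}
        for idx, entry in enumerate(lexicon):
            for s, cs in zip(entry.match_strings, entry.case_sensitive):
                flags = 0 if cs else re.IGNORECASE
                # lookahead capture: report every start, including overlapping
                # occurrences of the same string; the right boundary is
                # checked on the captured span (the lookahead consumes nothing)
                pat = re.compile(_BOUNDARY_L + "(?=(" + re.escape(s) + "))", flags)
                self.strings.append(_CompiledString(entry.target_id, s, idx, pat))
                owners.setdefault(s.lower(), []).append(entry.target_id)
        #: match strings claimed by more than one target (case-folded key)
        self.collisions: dict[str, list[str]] = {
            s: sorted(set(ts)) for s, ts in owners.items() if len(set(ts)) > 1
        }


def _candidate_matches(text: str, compiled: CompiledLexicon):
    """All boundary-valid (start, end, target, lexicon_index, string) tuples."""
    out = []
    for cs in compiled.strings:
        L = len(cs.string)
        for m in cs.pattern.finditer(text):
            start = m.start(1)
            end = start + L
            # right boundary: next char (if any) must not be alphanumeric
            if end < len(text) and text[end].isalnum() and text[end].isascii():
                continue
            out.append((start, end, cs.target_id, cs.lexicon_index, cs.string))
    return out


def _resolve_overlaps(candidates):
    """Greedy selection: longest first, then leftmost, then lexicon order.

    Candidates with an identical span are one surface match claimed by
    several strings/targets (a symbol collision): all of them are kept and
    co-attributed, mirroring the absence of contextual disambiguation.
    """
    ordered = sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[3]))
    taken: list[tuple[int, int, str, int, str]] = []
    occupied: set[tuple[int, int]] = set()
    for cand in ordered:
        s, e = cand[0], cand[1]
        if (s, e) in occupied:
            taken.append(cand)
            continue
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        taken.append(cand)
        occupied.add((s, e))
    return taken


def tag_text(text: str, compiled: CompiledLexicon) -> set[str]:
    """Targets with at least one resolved, non-blacklisted match in ``text``."""
    resolved = _resolve_overlaps(_candidate_matches(text, compiled))
    blacklist = compiled.lexicon.blacklist
    hits: set[str] = set()
    for _, _, target_id, _, string in resolved:
        blocked = False
        for bl_string, bl_context in blacklist:
            if bl_string.lower() != string.lower():
                continue
            if bl_context in ("", "*") or bl_context in text:
                blocked = True
                break
        if not blocked:
            hits.add(target_id)
    return hits


def tag_document(
    doc: DocumentRecord,
    lexicon: TargetLexicon | CompiledLexicon,
    scope: set[str] = frozenset(("title", "abstract", "fulltext")),
) -> set[str]:
    """Targets mentioned in any in-scope text unit of one document."""
    if not scope:
        raise CorpusValidationError("scope must name at least one text unit")
    unknown = set(scope) - set(TEXT_UNIT_NAMES)
    if unknown:
        raise CorpusValidationError(f"unknown text units in scope: {sorted(unknown)}")
    compiled = lexicon if isinstance(lexicon, CompiledLexicon) else CompiledLexicon(lexicon)
    hits: set[str] = set()
    for unit in TEXT_UNIT_NAMES:
        if unit in scope and unit in doc.text_units:
            hits |= tag_text(doc.text_units[unit], compiled)
    return hits


@dataclass
class DocumentTargetMatrix:
    """Binary document x target occurrence matrix (rows follow corpus order)."""

    doc_ids: list[str]
    target_ids: list[str]
    occurrence: np.ndarray  # uint8, shape (n_docs, n_targets)
    corpus_label: str = ""

    def __post_init__(self) -> None:
        self.occurrence = np.asarray(self.occurrence, dtype=np.uint8)
        if self.occurrence.shape != (len(self.doc_ids), len(self.target_ids)):
            raise CorpusValidationError("matrix shape does not match id lists")
        if not np.isin(self.occurrence, (0, 1)).all():
            raise CorpusValidationError("occurrence entries must be 0/1")

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def doc_counts(self) -> pd.Series:
        """Documents-per-target column sums, indexed by target id."""
        return pd.Series(self.occurrence.sum(axis=0), index=self.target_ids, dtype=int)

    def targets_of(self, doc_id: str) -> set[str]:
        row = self.occurrence[self.doc_ids.index(doc_id)]
        return {t for t, v in zip(self.target_ids, row) if v}

    def identified_targets(self) -> set[str]:
        """Targets mentioned in at least one document."""
        return set(self.doc_counts()[lambda s: s > 0].index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occurrence, index=self.doc_ids, columns=self.target_ids)

    @classmethod
    def from_mentions(
        cls, doc_ids: list[str], mentions: dict[str, set[str]],
        target_ids: list[str] | None = None, corpus_label: str = "",
    ) -> "DocumentTargetMatrix":
        """Build a matrix from per-document target sets.

        When ``target_ids`` is omitted, columns are the targets mentioned at
        least once, in sorted order (never-matched targets are dropped).
        """
        if target_ids is None:
            target_ids = sorted(set().union(*mentions.values()) if mentions else set())
        index = {t: j for j, t in enumerate(target_ids)}
        occ = np.zeros((len(doc_ids), len(target_ids)), dtype=np.uint8)
        for i, doc_id in enumerate(doc_ids):
            for t in mentions.get(doc_id, ()):
                if t in index:
                    occ[i, index[t]] = 1
        return cls(list(doc_ids), list(target_ids), occ, corpus_label)


def tag_corpus(
    corpus: Corpus,
    lexicon: TargetLexicon | CompiledLexicon,
    scope: set[str] = frozenset(("title", "abstract", "fulltext")),
) -> DocumentTargetMatrix:
    """Tag every document; columns cover targets matched at least once."""
    compiled = lexicon if isinstance(lexicon, CompiledLexicon) else CompiledLexicon(lexicon)
    mentions = {doc.doc_id: tag_document(doc, compiled, scope) for doc in corpus}
    return DocumentTargetMatrix.from_mentions(
        corpus.doc_ids, mentions, corpus_label=corpus.label
    )


# ---------------------------------------------------------------------------
# Evaluation against curated gold standards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaggingMetrics:
    """Recall / precision / F of tagging against a curated gold standard.

    F = 2 * recall * precision / (recall + precision) when the denominator is
    positive, else 0.  Precision is NaN when the gold standard is not asserted
    to be exhaustive (curated links list true mentions but not all of them).
    """

    recall: float
    precision: float
    f_measure: float
    true_positives: int
    false_negatives: int
    false_positives: int


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (0 when both are 0)."""
    if np.isnan(recall) or np.isnan(precision):
        return float("nan")
    if recall + precision <= 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def evaluate_against_gold(
    matrix: DocumentTargetMatrix,
    gold: GoldStandard,
    level: str = "target_set",
    gold_exhaustive: bool = False,
) -> TaggingMetrics:
    """Compare tagging output with curated document–gene links.

    ``target_set`` level: recall over unique gold targets identified anywhere
    in the corpus (the curated-database comparison); precision requires an
    exhaustive gold set and is NaN otherwise.  ``pair`` level: recall (and,
    when exhaustive, precision) over (document, target) pairs restricted to
    gold documents present in the matrix.
    """
    if len(gold) == 0:
        raise CorpusValidationError("gold standard must be non-empty")
    if level not in ("target_set", "pair"):
        raise CorpusValidationError(f"unknown evaluation level {level!r}")

    if level == "target_set":
        identified = matrix.identified_targets()
        gold_targets = gold.target_ids
        tp = len(identified & gold_targets)
        fn = len(gold_targets - identified)
        fp = len(identified - gold_targets)
        recall = tp / len(gold_targets)
    else:
        doc_set = set(matrix.doc_ids)
        gold_pairs = {(d, t) for d, t in gold.pairs if d in doc_set}
        if not gold_pairs:
            raise CorpusValidationError("no gold documents present in the matrix")
        found_pairs = {
            (d, t)
            for i, d in enumerate(matrix.doc_ids)
            for t, v in zip(matrix.target_ids, matrix.occurrence[i])
            if v
        }
        tp = len(found_pairs & gold_pairs)
        fn = len(gold_pairs - found_pairs)
        fp = len(found_pairs - gold_pairs)
        recall = tp / len(gold_pairs)

    if gold_exhaustive:
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    else:
        precision = float("nan")
    return TaggingMetrics(
        recall=recall,
        precision=precision,
        f_measure=f_measure(recall, precision),
        true_positives=tp,
        false_negatives=fn,
        false_positives=fp,
    )


@dataclass(frozen=True)
class MergeCounts:
    n_identified: int
    n_gold: int
    n_overlap: int
    n_merged: int


def merge_curated_targets(
    identified: set[str], gold_targets: set[str]
) -> tuple[set[str], MergeCounts]:
    """Union the tagged target set with curated gold targets.

    Targets present in the curated database but missed by the tagger are added
    to the working target set; the counts record documents the bookkeeping.
    """
    merged = set(identified) | set(gold_targets)
    counts = MergeCounts(
        n_identified=len(identified),
        n_gold=len(gold_targets),
        n_overlap=len(set(identified) & set(gold_targets)),
        n_merged=len(merged),
    )
    return merged, counts


# ---------------------------------------------------------------------------
# Matrix serialization: sparse triplet TSV with a sidecar header line
# ---------------------------------------------------------------------------

def write_matrix(matrix: DocumentTargetMatrix, path) -> None:
    """Sparse triplet TSV: header comment with dims/ids, then doc/target/1 rows."""
    from pathlib import Path

    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#label\t{matrix.corpus_label}\n")
        fh.write("#docs\t" + "\t".join(matrix.doc_ids) + "\n")
        fh.write("#targets\t" + "\t".join(matrix.target_ids) + "\n")
        rows, cols = np.nonzero(matrix.occurrence)
        for i, j in zip(rows, cols):
            fh.write(f"{matrix.doc_ids[i]}\t{matrix.target_ids[j]}\t1\n")


def read_matrix(path) -> DocumentTargetMatrix:
    from pathlib import Path

    path = Path(path)
    label, doc_ids, target_ids = "", [], []
    triples: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#label\t"):
                label = line.split("\t", 1)[1]
            elif line.startswith("#docs\t"):
                doc_ids = line.split("\t")[1:]
            elif line.startswith("#targets\t"):
                target_ids = line.split("\t")[1:]
            else:
                d, t, _ = line.split("\t")
                triples.append((d, t))
    mentions: dict[str, set[str]] = {}
    for d, t in triples:
        mentions.setdefault(d, set()).add(t)
    return DocumentTargetMatrix.from_mentions(doc_ids, mentions, target_ids, label)
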