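"""Corpus, lexicon and gold-standard data model with file I/O.

A *corpus* is an ordered collection of publication records, each carrying the
bibliographic triple (journal, volume, issue), a set of controlled index terms
(MeSH-style), and one or more text units ("title", "abstract", "fulltext").
The triple drives issue-matched background sampling; the index terms define
topic membership; the text units feed the dictionary tagger.

A *target lexicon* maps canonical gene symbols to their literature match
strings (synonyms, product names, common abbreviations), mirroring the
symbol / name / match-strings layout of curated gene dictionaries.  A *gold
standard* is a set of curated (document, gene) links used to estimate tagger
recall.

Corpora are stored as JSON-lines (one document object per line; text units
need nesting); lexicons and gold standards as tab-delimited text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

TEXT_UNIT_NAMES = ("title", "abstract", "fulltext")


class CorpusFormatError(ValueError):
    """Raised when an input file cannot be parsed into the data model."""


class CorpusValidationError(ValueError):
    """Raised when parsed data violates a model invariant."""


@dataclass(frozen=True)
class DocumentRecord:
    """One publication: identifiers, issue triple, index terms, text units."""

    doc_id: str
    journal: str
    volume: str
    issue: str
    mesh_terms: frozenset[str] = frozenset()
    text_units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusValidationError("doc_id must be non-empty")
        for name in ("journal", "volume", "issue"):
            if not getattr(self, name):
                raise CorpusValidationError(
                    f"document {self.doc_id!r}: {name} must be non-empty"
                )
        if not self.text_units:
            raise CorpusValidationError(
                f"document {self.doc_id!r}: at least one text unit required"
            )
        unknown = set(self.text_units) - set(TEXT_UNIT_NAMES)
        if unknown:
            raise CorpusValidationError(
                f"document {self.doc_id!r}: unknown text units {sorted(unknown)}"
            )
        object.__setattr__(self, "mesh_terms", frozenset(self.mesh_terms))
        object.__setattr__(self, "text_units", dict(self.text_units))

    @property
    def issue_key(self) -> tuple[str, str, str]:
        """The (journal, volume, issue) triple used for background matching."""
        return (self.journal, self.volume, self.issue)

    def text(self, scope: Iterable[str]) -> str:
        """Concatenate the in-scope text units (newline-joined, stable order)."""
        return "\n".join(
            self.text_units[u] for u in TEXT_UNIT_NAMES
            if u in scope and u in self.text_units
        )


@dataclass
class Corpus:
    """Ordered document collection with unique ids."""

    documents: list[DocumentRecord]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.documents:
            raise CorpusValidationError("corpus must contain at least one document")
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
        self._by_id = {d.doc_id: d for d in self.documents}

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self.documents)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._by_id

    def __getitem__(self, doc_id: str) -> DocumentRecord:
        return self._by_id[doc_id]

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    def by_issue(self) -> dict[tuple[str, str, str], list[DocumentRecord]]:
        """Group documents by (journal, volume, issue), preserving order."""
        groups: dict[tuple[str, str, str], list[DocumentRecord]] = {}
        for doc in self.documents:
            groups.setdefault(doc.issue_key, []).append(doc)
        return groups


@dataclass(frozen=True)
class LexiconEntry:
    """One canonical target symbol with its literature match strings.

    ``case_sensitive`` carries one flag per match string (parallel tuple).
    """

    target_id: str
    name: str
    match_strings: tuple[str, ...]
    case_sensitive: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not self.target_id:
            raise CorpusValidationError("target_id must be non-empty")
        if not self.match_strings:
            raise CorpusValidationError(
                f"lexicon entry {self.target_id!r}: at least one match string required"
            )
        if any(not s.strip() for s in self.match_strings):
            raise CorpusValidationError(
                f"lexicon entry {self.target_id!r}: empty match string"
            )
        if len(self.case_sensitive) != len(self.match_strings):
            raise CorpusValidationError(
                f"lexicon entry {self.target_id!r}: case flags do not align"
            )


def default_case_sensitive(match_string: str) -> bool:
    """Default case rule for gene-symbol matching.

    Short strings (<= 4 characters) and strings containing a digit are treated
    as symbols and matched case-sensitively (``CAT`` the gene is not ``cat``
    the animal); longer plain strings such as ``catalase`` behave like common
    nouns and match case-insensitively.
    """
    return len(match_string) <= 4 or any(ch.isdigit() for ch in match_string)


@dataclass
class TargetLexicon:
    """Collection of lexicon entries plus a match blacklist.

    The blacklist holds (match_string, context) pairs modelling manual review:
    a match of ``match_string`` is discarded when ``context`` is empty/``"*"``
    (always discard) or when the context substring occurs in the same text.
    """

    entries: list[LexiconEntry]
    blacklist: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            if entry.target_id in seen:
                raise CorpusValidationError(
                    f"duplicate target_id {entry.target_id!r} in lexicon"
                )
            seen.add(entry.target_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    @property
    def target_ids(self) -> list[str]:
        return [e.target_id for e in self.entries]


@dataclass
class GoldStandard:
    """Curated (doc_id, target_id) links, e.g. an expert gene–paper table."""

    pairs: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)

    @property
    def target_ids(self) -> set[str]:
        return {t for _, t in self.pairs}

    @property
    def doc_ids(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _document_to_json(doc: DocumentRecord) -> dict:
    return {
        "doc_id": doc.doc_id,
        "journal": doc.journal,
        "volume": doc.volume,
        "issue": doc.issue,
        "mesh_terms": sorted(doc.mesh_terms),
        "text_units": dict(doc.text_units),
    }


def _document_from_json(obj: dict, where: str) -> DocumentRecord:
    required = ("doc_id", "journal", "volume", "issue")
    missing = [k for k in required if k not in obj]
    if missing:
        raise CorpusFormatError(f"{where}: missing fields {missing}")
    try:
        return DocumentRecord(
            doc_id=str(obj["doc_id"]),
            journal=str(obj["journal"]),
            volume=str(obj["volume"]),
            issue=str(obj["issue"]),
            mesh_terms=frozenset(obj.get("mesh_terms", ())),
            text_units=dict(obj.get("text_units", {})),
        )
    except CorpusValidationError as exc:
        raise CorpusValidationError(f"{where}: {exc}") from exc


def read_corpus(path: str | Path, format: str = "jsonl", label: str | None = None) -> Corpus:
    """Read a corpus from disk.

    ``jsonl``: one JSON document object per line.  ``tsv``: metadata-only
    corpora with columns doc_id/journal/volume/issue/mesh_terms/title
    (mesh terms semicolon-delimited); the title column doubles as the single
    text unit.
    """
    path = Path(path)
    docs: list[DocumentRecord] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                docs.append(_document_from_json(obj, f"{path}:{lineno}"))
    elif format == "tsv":
        with path.open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for col in ("doc_id", "journal", "volume", "issue", "title"):
                if col not in idx:
                    raise CorpusFormatError(f"{path}: missing column {col!r}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < len(header):
                    raise CorpusFormatError(f"{path}:{lineno}: expected {len(header)} columns")
                mesh = fields[idx["mesh_terms"]] if "mesh_terms" in idx else ""
                docs.append(DocumentRecord(
                    doc_id=fields[idx["doc_id"]],
                    journal=fields[idx["journal"]],
                    volume=fields[idx["volume"]],
                    issue=fields[idx["issue"]],
                    mesh_terms=frozenset(t for t in mesh.split(";") if t),
                    text_units={"title": fields[idx["title"]]},
                ))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return Corpus(documents=docs, label=label if label is not None else path.stem)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON-lines (sorted keys; stable byte output)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(_document_to_json(doc), sort_keys=True) + "\n")


def read_lexicon(path: str | Path) -> TargetLexicon:
    """Read a 3+-column lexicon TSV: symbol, name, pipe-delimited match strings.

    An optional fourth column carries explicit per-string case flags
    (pipe-delimited ``cs``/``ci``); otherwise :func:`default_case_sensitive`
    applies.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    entries: list[LexiconEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise CorpusFormatError(f"{path}:{lineno}: expected >= 3 columns")
            symbol, name, raw_strings = fields[0], fields[1], fields[2]
            strings = tuple(s.strip() for s in raw_strings.split("|") if s.strip())
            if not strings:
                raise CorpusValidationError(
                    f"{path}:{lineno}: no match strings for {symbol!r}"
                )
            if len(fields) >= 4 and fields[3].strip():
                flags_raw = [f.strip() for f in fields[3].split("|") if f.strip()]
                if len(flags_raw) != len(strings):
                    raise CorpusFormatError(
                        f"{path}:{lineno}: case flags do not align with match strings"
                    )
                flags = tuple(f == "cs" for f in flags_raw)
            else:
                flags = tuple(default_case_sensitive(s) for s in strings)
            entries.append(LexiconEntry(symbol, name, strings, flags))
    return TargetLexicon(entries=entries)


def write_lexicon(lexicon: TargetLexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in lexicon:
            flags = "|".join("cs" if f else "ci" for f in e.case_sensitive)
            fh.write(f"{e.target_id}\t{e.name}\t{'|'.join(e.match_strings)}\t{flags}\n")


def read_gold(path: str | Path, provenance: str = "") -> GoldStandard:
    """Read a 2-column (doc_id, target_id) TSV; duplicate pairs collapse."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise CorpusFormatError(f"{path}:{lineno}: expected 2 columns")
            pairs.add((fields[0], fields[1]))
    return GoldStandard(pairs=frozenset(pairs), provenance=provenance or str(path))


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc_id, target_id in sorted(gold.pairs):
            fh.write(f"{doc_id}\t{target_id}\n")
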