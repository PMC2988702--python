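"""Gene-set (term) over-representation analysis of a target list.

Given an annotation catalog (GO/pathway-style terms with their annotated gene
sets, read from GMT), a target list of size n drawn from a universe of N
genes is tested per term: with K universe genes annotated to the term and k
of the targets among them, the one-sided (upper-tail) exact test gives the
probability of observing at least k annotated targets by chance, and fold
enrichment is (k/n)/(K/N).  Benjamini–Hochberg adjustment is applied within
each annotation namespace (e.g. the molecular-function terms form one family,
pathways another), matching how such catalogs are conventionally reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus import CorpusValidationError
from .stats import ContingencyTable, bh_adjust, fisher_exact

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    namespace: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise CorpusValidationError(f"term {self.term_id!r} has an empty gene set")


@dataclass
class AnnotationCatalog:
    """term_id -> (name, namespace, annotated gene set)."""

    terms: dict[str, AnnotationTerm] = field(default_factory=dict)

    def add(self, term: AnnotationTerm) -> None:
        if term.term_id in self.terms:
            raise CorpusValidationError(f"duplicate term_id {term.term_id!r}")
        self.terms[term.term_id] = term

    def __len__(self) -> int:
        return len(self.terms)

    def namespaces(self) -> list[str]:
        return sorted({t.namespace for t in self.terms.values()})


def read_gene_sets(path: str | Path, namespace: str | None = None) -> AnnotationCatalog:
    """Read a GMT file: term, description, then tab-separated member genes.

    Duplicate genes within a term collapse; a term with no genes is a parse
    error.  When ``namespace`` is None the description field doubles as the
    namespace (conventional for mixed catalogs), so one file can carry
    several BH families.
    """
    path = Path(path)
    catalog = AnnotationCatalog()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term_id, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term_id!r} has no genes")
            catalog.add(AnnotationTerm(
                term_id=term_id,
                name=description,
                namespace=namespace if namespace is not None else description or "default",
                genes=genes,
            ))
    return catalog


def write_gene_sets(catalog: AnnotationCatalog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for term_id in sorted(catalog.terms):
            t = catalog.terms[term_id]
            fh.write("\t".join([t.term_id, t.namespace, *sorted(t.genes)]) + "\n")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): target-list annotation rate over universe rate."""
    if K == 0 or n == 0:
        return float("nan")
    return (k / n) / (K / N)


def enrich(
    targets: set[str],
    catalog: AnnotationCatalog,
    universe: set[str],
    sidedness: str = "greater",
) -> pd.DataFrame:
    """Term-level over-representation of ``targets`` within ``universe``.

    Targets must lie in the universe; term gene sets are intersected with the
    universe before testing (genes outside it are dropped with a logged
    count).  BH runs within each namespace; results are sorted by p
    ascending.  Columns: term_id, name, namespace, k, n, K, N, p, p_bh, fold.
    """
    if not universe:
        raise CorpusValidationError("universe must be non-empty")
    if not targets:
        raise CorpusValidationError("target list must be non-empty")
    stray = set(targets) - set(universe)
    if stray:
        raise CorpusValidationError(
            f"targets outside the universe: {sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(targets)
    rows = []
    dropped = 0
    for term_id in sorted(catalog.terms):
        term = catalog.terms[term_id]
        annotated = term.genes & universe
        dropped += len(term.genes) - len(annotated)
        if not annotated:
            continue
        K = len(annotated)
        k = len(annotated & targets)
        if N == n:
            p = 1.0  # target list is the whole universe: a forced draw
        else:
            table = ContingencyTable(k, n - k, K - k, (N - n) - (K - k))
            p = fisher_exact(table, sidedness).p_value
        rows.append({
            "term_id": term.term_id, "name": term.name, "namespace": term.namespace,
            "k": k, "n": n, "K": K, "N": N,
            "p": p, "fold": fold_enrichment(k, n, K, N),
        })
    if dropped:
        logger.info("enrichment: dropped %d annotated gene(s) outside the universe", dropped)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_bh"] = float("nan")
    for ns, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "p_bh"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    return df.sort_values("p", kind="stable").reset_index(drop=True)
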