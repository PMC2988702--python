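"""Issue-matched background corpus construction and homogeneity checks.

A topic corpus is defined by controlled index terms (e.g. two MeSH headings).
To contrast its gene-mention frequencies against "everything else published
in the same venues", each foreground document is paired with one randomly
chosen document from the *same journal, volume and issue* that does NOT carry
any of the excluded index terms.  Sampling is without replacement within a
background set (a background document serves at most one foreground
document), and independent background sets are drawn with distinct seeds.

The homogeneity test checks that independently drawn background sets are
statistically exchangeable: for every target and every pair of sets, a
two-sided exact test on documents-with vs documents-without, followed by a
single Benjamini–Hochberg adjustment over all (target, pair) tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Corpus, CorpusValidationError, DocumentRecord
from .stats import ContingencyTable, bh_adjust, fisher_exact
from .tagging import DocumentTargetMatrix

logger = logging.getLogger(__name__)

FALLBACK_POLICIES = ("skip", "strict", "widen_volume")


class SamplingError(RuntimeError):
    """Raised under the strict fallback policy when no companion exists."""


@dataclass(frozen=True)
class BackgroundSpec:
    """How to build background sets: exclusions, multiplicity, seeds, fallback."""

    excluded_mesh: frozenset[str]
    n_sets: int = 3
    seeds: tuple[int, ...] = (101, 102, 103)
    fallback: str = "skip"

    def __post_init__(self) -> None:
        if not self.excluded_mesh:
            raise CorpusValidationError("excluded_mesh must be non-empty")
        if self.n_sets < 1:
            raise CorpusValidationError("n_sets must be >= 1")
        if len(self.seeds) != self.n_sets:
            raise CorpusValidationError("one seed per background set required")
        if len(set(self.seeds)) != len(self.seeds):
            raise CorpusValidationError("seeds must be distinct")
        if self.fallback not in FALLBACK_POLICIES:
            raise CorpusValidationError(f"unknown fallback policy {self.fallback!r}")
        object.__setattr__(self, "excluded_mesh", frozenset(self.excluded_mesh))


@dataclass
class BackgroundSet:
    """One matched background corpus plus its foreground->background pairing."""

    corpus: Corpus
    matching: dict[str, str]
    seed: int
    skipped: list[str] = field(default_factory=list)
    widened: list[str] = field(default_factory=list)


def eligible_documents(
    universe: Corpus,
    seed_doc: DocumentRecord,
    excluded_mesh: frozenset[str] | set[str],
    same_issue: bool = True,
) -> list[str]:
    """Companion documents for one foreground document, sorted by doc_id.

    Companions share the seed document's (journal, volume, issue) triple
    (volume only, when ``same_issue`` is false), carry none of the excluded
    index terms, and never include the seed document itself.
    """
    if seed_doc.doc_id not in universe:
        raise CorpusValidationError(
            f"seed document {seed_doc.doc_id!r} not in the universe corpus"
        )
    excluded = frozenset(excluded_mesh)
    out = []
    for doc in universe:
        if doc.doc_id == seed_doc.doc_id:
            continue
        if doc.journal != seed_doc.journal or doc.volume != seed_doc.volume:
            continue
        if same_issue and doc.issue != seed_doc.issue:
            continue
        if doc.mesh_terms & excluded:
            continue
        out.append(doc.doc_id)
    return sorted(out)


def sample_background_set(
    universe: Corpus,
    foreground: Corpus,
    spec: BackgroundSpec,
    seed: int,
) -> BackgroundSet:
    """Draw one issue-matched background set (seeded, without replacement).

    Foreground documents are visited in corpus order; each draws uniformly at
    random from its remaining eligible companions.  A foreground document with
    no remaining companion is handled per ``spec.fallback``: ``skip`` drops
    the pair (logged), ``strict`` raises, ``widen_volume`` relaxes matching to
    the same journal+volume.
    """
    missing = [d.doc_id for d in foreground if d.doc_id not in universe]
    if missing:
        raise CorpusValidationError(
            f"foreground documents not in universe: {missing[:5]}"
        )
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    matching: dict[str, str] = {}
    skipped: list[str] = []
    widened: list[str] = []
    chosen_docs: list[DocumentRecord] = []
    for fg_doc in foreground:
        pool = [
            d for d in eligible_documents(universe, fg_doc, spec.excluded_mesh)
            if d not in used
        ]
        if not pool and spec.fallback == "widen_volume":
            pool = [
                d for d in eligible_documents(
                    universe, fg_doc, spec.excluded_mesh, same_issue=False
                )
                if d not in used
            ]
            if pool:
                widened.append(fg_doc.doc_id)
        if not pool:
            if spec.fallback == "strict":
                raise SamplingError(
                    f"no eligible background companion for {fg_doc.doc_id!r}"
                )
            skipped.append(fg_doc.doc_id)
            logger.info("background sampling: skipped foreground doc %s", fg_doc.doc_id)
            continue
        pick = pool[int(rng.integers(len(pool)))]
        used.add(pick)
        matching[fg_doc.doc_id] = pick
        chosen_docs.append(universe[pick])
    if not chosen_docs:
        raise SamplingError("background set is empty: no foreground document had a companion")
    corpus = Corpus(documents=chosen_docs, label=f"background_seed{seed}")
    return BackgroundSet(corpus=corpus, matching=matching, seed=seed,
                         skipped=skipped, widened=widened)


def sample_backgrounds(
    universe: Corpus, foreground: Corpus, spec: BackgroundSpec
) -> list[BackgroundSet]:
    """Draw ``spec.n_sets`` independent background sets, one per seed."""
    return [
        sample_background_set(universe, foreground, spec, seed) for seed in spec.seeds
    ]


def check_background_set(
    bg: BackgroundSet,
    universe: Corpus,
    foreground: Corpus,
    spec: BackgroundSpec,
) -> None:
    """Independently assert every invariant of a sampled background set.

    Raises :class:`CorpusValidationError` on any violation; used post-hoc in
    tests and after pipeline sampling as a safety net.
    """
    if len(bg.corpus) > len(foreground):
        raise CorpusValidationError("background larger than foreground")
    seen: set[str] = set()
    for fg_id, bg_id in bg.matching.items():
        if bg_id in seen:
            raise CorpusValidationError(f"background doc {bg_id!r} used twice")
        seen.add(bg_id)
        fg_doc, bg_doc = foreground[fg_id], universe[bg_id]
        widened = fg_id in bg.widened
        same = (fg_doc.journal == bg_doc.journal and fg_doc.volume == bg_doc.volume
                and (widened or fg_doc.issue == bg_doc.issue))
        if not same:
            raise CorpusValidationError(
                f"pair {fg_id!r}->{bg_id!r} does not share the issue triple"
            )
        if bg_doc.mesh_terms & spec.excluded_mesh:
            raise CorpusValidationError(
                f"background doc {bg_id!r} carries an excluded index term"
            )
        if bg_id == fg_id:
            raise CorpusValidationError("foreground document matched to itself")
    if set(bg.corpus.doc_ids) != set(bg.matching.values()):
        raise CorpusValidationError("matching and corpus membership disagree")


def overlap_counts(doc_id_sets: list[set[str]]) -> dict[int, int]:
    """Documents shared by exactly m of the k sets, for m = 1..k.

    Reproduces the structure of a k-set Venn diagram over background draws.
    """
    counts: dict[str, int] = {}
    for s in doc_id_sets:
        for d in s:
            counts[d] = counts.get(d, 0) + 1
    out = {m: 0 for m in range(1, len(doc_id_sets) + 1)}
    for m in counts.values():
        out[m] += 1
    return out


def background_homogeneity_test(
    matrices: list[DocumentTargetMatrix], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise exchangeability test of independently drawn background sets.

    For each target observed in any set and each pair of sets, a two-sided
    exact test on the 2x2 table (docs with / without the target) x (set A /
    set B); one BH adjustment spans all (target, pair) tests.  Returns a
    table with columns target_id, set_a, set_b, a..d, p, p_bh, significant.
    """
    if len(matrices) < 2:
        raise CorpusValidationError("homogeneity test requires >= 2 matrices")
    counts = [m.doc_counts() for m in matrices]
    sizes = [m.n_docs for m in matrices]
    targets = sorted(set().union(*(set(c.index) for c in counts)))
    rows = []
    for t in targets:
        for i, j in itertools.combinations(range(len(matrices)), 2):
            a = int(counts[i].get(t, 0))
            c = int(counts[j].get(t, 0))
            table = ContingencyTable(a, sizes[i] - a, c, sizes[j] - c)
            res = fisher_exact(table, "two_sided")
            rows.append({
                "target_id": t, "set_a": i, "set_b": j,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "p": res.p_value,
            })
    df = pd.DataFrame(rows)
    df["p_bh"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p_bh"] < alpha
    return df
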