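"""Foreground-vs-background target over-representation with consensus selection.

A target's *document frequency* is the number of documents mentioning it at
least once divided by the corpus size.  For every target observed in either
corpus, a 2x2 table (foreground with/without x background with/without) feeds
a two-sided exact test; Benjamini–Hochberg adjustment spans all targets of
one foreground-vs-background comparison.  Across k independent background
sets, the *consensus rule* selects a target when its raw p is below
``alpha_raw`` in all k comparisons AND its BH-adjusted p is below
``alpha_bh`` in at least ``min_bh_sets`` of them.  Selected targets are
ranked by the ascending geometric mean of their k raw p-values (ties broken
by foreground document count descending, then symbol).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .corpus import CorpusValidationError
from .stats import ContingencyTable, bh_adjust, fisher_exact
from .tagging import DocumentTargetMatrix

#: floor applied inside the geometric-mean ranking to avoid log(0)
P_FLOOR = 1e-300


@dataclass(frozen=True)
class TargetFrequency:
    """Documents-with-target count and its fraction of the corpus."""

    target_id: str
    doc_count: int
    corpus_size: int

    @property
    def frequency(self) -> float:
        return self.doc_count / self.corpus_size


def target_frequencies(matrix: DocumentTargetMatrix) -> list[TargetFrequency]:
    """Per-target document counts/frequencies from an occurrence matrix."""
    if matrix.n_docs == 0 or matrix.n_targets == 0:
        raise CorpusValidationError("matrix must have at least one document and target")
    counts = matrix.doc_counts()
    return [
        TargetFrequency(t, int(counts[t]), matrix.n_docs) for t in matrix.target_ids
    ]


@lru_cache(maxsize=200_000)
def _cached_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    return fisher_exact(ContingencyTable(a, b, c, d), "two_sided").p_value


def overrep_test(
    fg: DocumentTargetMatrix, bg: DocumentTargetMatrix
) -> pd.DataFrame:
    """Exact tests of every target's frequency, foreground vs one background.

    Returns a table indexed by target_id with columns a, b, c, d, p, p_bh
    (a = foreground docs with the target, c = background docs with it); the
    tested universe is the union of targets observed in either corpus, and
    the BH family is all targets of this one comparison.
    """
    targets = sorted(set(fg.target_ids) | set(bg.target_ids))
    if not targets:
        raise CorpusValidationError("no targets observed in either corpus")
    fg_counts, bg_counts = fg.doc_counts(), bg.doc_counts()
    n_fg, n_bg = fg.n_docs, bg.n_docs
    rows = []
    for t in targets:
        a = int(fg_counts.get(t, 0))
        c = int(bg_counts.get(t, 0))
        p = _cached_two_sided_p(a, n_fg - a, c, n_bg - c)
        rows.append({"a": a, "b": n_fg - a, "c": c, "d": n_bg - c, "p": p})
    df = pd.DataFrame(rows, index=pd.Index(targets, name="target_id"))
    df["p_bh"] = bh_adjust(df["p"].to_numpy())
    return df


def consensus_select(
    comparisons: list[pd.DataFrame],
    alpha_raw: float = 0.05,
    alpha_bh: float = 0.05,
    min_bh_sets: int = 2,
    require_all_raw: bool = True,
) -> pd.DataFrame:
    """Apply the multi-background consensus rule and rank the selections.

    ``comparisons`` holds one :func:`overrep_test` table per background set
    over a common target universe.  A target is selected when (optionally) its
    raw p is below ``alpha_raw`` in every comparison and its BH-adjusted p is
    below ``alpha_bh`` in at least ``min_bh_sets`` comparisons.  The returned
    table carries per-set p columns, the selection flag, the geometric mean
    of raw p-values, foreground doc count, and 1-based ranks for selected
    targets (NA elsewhere).
    """
    k = len(comparisons)
    if k < min_bh_sets:
        raise CorpusValidationError(
            f"need at least min_bh_sets={min_bh_sets} comparisons, got {k}"
        )
    universe = set(comparisons[0].index)
    for comp in comparisons[1:]:
        if set(comp.index) != universe:
            raise CorpusValidationError(
                "comparisons cover inconsistent target universes"
            )
    targets = sorted(universe)
    out = pd.DataFrame(index=pd.Index(targets, name="target_id"))
    raw = np.column_stack([c.loc[targets, "p"].to_numpy() for c in comparisons])
    adj = np.column_stack([c.loc[targets, "p_bh"].to_numpy() for c in comparisons])
    out["fg_count"] = comparisons[0].loc[targets, "a"].to_numpy()
    for i in range(k):
        out[f"p_bg{i + 1}"] = raw[:, i]
        out[f"p_bh_bg{i + 1}"] = adj[:, i]
    raw_ok = (raw < alpha_raw).all(axis=1) if require_all_raw else np.ones(len(targets), bool)
    bh_ok = (adj < alpha_bh).sum(axis=1) >= min_bh_sets
    out["selected"] = raw_ok & bh_ok
    out["p_geomean"] = np.exp(np.log(np.clip(raw, P_FLOOR, None)).mean(axis=1))

    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    sel = out[out["selected"]].sort_values(
        by=["p_geomean", "fg_count", "target_id"], ascending=[True, False, True]
    )
    out.loc[sel.index, "rank"] = np.arange(1, len(sel) + 1)
    return out


def selected_table(consensus: pd.DataFrame) -> pd.DataFrame:
    """The ranked selected-target table (rank ascending)."""
    return consensus[consensus["selected"]].sort_values("rank")
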