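"""Seeded generators for every input the pipeline consumes.

The generator emulates the statistical structure the analysis assumes, not
the surface form of real articles.  A publication *universe* is organised
into journal/volume/issue groups; a *foreground* subset carries the excluded
topic index terms (so the background sampler's exclusion logic is exercised
exactly as in a real topic query).  Per document, each lexicon target is
mentioned independently: planted targets with an elevated probability in the
foreground and a lower probability elsewhere, all other targets at a common
baseline rate everywhere.  Documents are bags of the mentioned targets' match
strings separated by filler tokens from a fixed non-matching vocabulary, so
the dictionary tagger can recover the truth table exactly.  The interaction
network is an Erdős–Rényi mixture with one densely connected planted module;
the annotation catalog carries one planted term overlapping the planted
targets.  All outputs are deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .corpus import (
    Corpus,
    CorpusValidationError,
    DocumentRecord,
    GoldStandard,
    LexiconEntry,
    TargetLexicon,
    write_corpus,
    write_gold,
    write_lexicon,
)
from .enrich import AnnotationCatalog, AnnotationTerm, write_gene_sets
from .network import InteractionNetwork, write_edge_list

_FILLER_VOCAB = (
    "cells signal pathway response model level effect study assay control "
    "membrane tissue growth factor binding expression analysis result method "
    "protein function role increase decrease treatment sample group data"
).split()


@dataclass(frozen=True)
class PlantedTarget:
    """A target with elevated mention probability in the foreground."""

    target_id: str
    foreground_prob: float
    background_prob: float

    def __post_init__(self) -> None:
        if not (0 <= self.background_prob <= self.foreground_prob <= 1):
            raise CorpusValidationError(
                f"planted target {self.target_id!r}: require "
                "0 <= background_prob <= foreground_prob <= 1"
            )


@dataclass(frozen=True)
class IssueStructure:
    """Journal/volume/issue layout of the publication universe."""

    n_journals: int = 10
    volumes_per_journal: int = 5
    issues_per_volume: int = 6
    docs_per_issue: int = 10

    @property
    def n_issues(self) -> int:
        return self.n_journals * self.volumes_per_journal * self.issues_per_volume

    @property
    def capacity(self) -> int:
        return self.n_issues * self.docs_per_issue


@dataclass(frozen=True)
class NetworkConfig:
    """Planted-module Erdős–Rényi mixture."""

    n_genes: int = 2000
    p_background_edge: float = 0.005
    module_size: int = 0  # 0 -> module = the planted targets only
    p_module_edge: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_background_edge", "p_module_edge"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CorpusValidationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AnnotationConfig:
    n_terms: int = 50
    term_size_min: int = 10
    term_size_max: int = 40
    planted_overlap_fraction: float = 0.6


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic run (defaults are the package's
    reference conditions: a 3,000-document universe with a 300-document topic
    foreground, 300 lexicon targets of which 12 are planted at a 4x
    foreground-to-background mention ratio)."""

    n_targets: int = 300
    n_synonyms_min: int = 1
    n_synonyms_max: int = 3
    universe_docs: int = 3000
    foreground_docs: int = 300
    issues: IssueStructure = field(default_factory=IssueStructure)
    excluded_mesh: tuple[str, ...] = ("Topic A", "Topic B")
    baseline_mention_prob: float = 0.03
    n_planted: int = 12
    planted_foreground_prob: float = 0.15
    planted_background_prob: float = 0.0375
    fulltext_fraction: float = 0.4
    abstract_mention_prob: float = 0.6  # P(mention visible in abstract | doc has fulltext)
    gold_pair_fraction: float = 0.3
    gold_missing_targets: int = 2
    network: NetworkConfig = field(default_factory=NetworkConfig)
    annotations: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.foreground_docs > self.universe_docs:
            raise CorpusValidationError("foreground_docs cannot exceed universe_docs")
        if self.universe_docs > self.issues.capacity:
            raise CorpusValidationError(
                f"universe_docs={self.universe_docs} exceeds the issue capacity "
                f"{self.issues.capacity}"
            )
        if self.n_planted > self.n_targets:
            raise CorpusValidationError("n_planted cannot exceed n_targets")
        for name in ("baseline_mention_prob", "planted_foreground_prob",
                     "planted_background_prob", "fulltext_fraction",
                     "abstract_mention_prob", "gold_pair_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CorpusValidationError(f"{name} must lie in [0, 1]")
        if self.planted_background_prob > self.planted_foreground_prob:
            raise CorpusValidationError(
                "planted_background_prob cannot exceed planted_foreground_prob"
            )
        if not self.excluded_mesh:
            raise CorpusValidationError("excluded_mesh must be non-empty")
        # every foreground doc needs a non-indexed companion in its issue;
        # capping the per-issue foreground load at half the issue size
        # guarantees one even under within-set no-replacement sampling
        cap = self.issues.docs_per_issue // 2
        if cap < 1:
            raise CorpusValidationError("docs_per_issue must be >= 2")
        if self.foreground_docs > cap * self.issues.n_issues:
            raise CorpusValidationError(
                "foreground_docs exceeds the per-issue foreground capacity"
            )


@dataclass
class GroundTruth:
    """What the generator planted; the key for recovery checks."""

    planted_targets: list[str]
    mentions: dict[str, set[str]]          # doc_id -> true mentioned targets
    abstract_mentions: dict[str, set[str]] # subset visible in title+abstract
    foreground_doc_ids: list[str]
    module_members: list[str]
    planted_term_id: str

    def to_json(self) -> str:
        obj = {
            "planted_targets": self.planted_targets,
            "mentions": {d: sorted(ts) for d, ts in sorted(self.mentions.items())},
            "abstract_mentions": {
                d: sorted(ts) for d, ts in sorted(self.abstract_mentions.items())
            },
            "foreground_doc_ids": self.foreground_doc_ids,
            "module_members": self.module_members,
            "planted_term_id": self.planted_term_id,
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            planted_targets=list(obj["planted_targets"]),
            mentions={d: set(ts) for d, ts in obj["mentions"].items()},
            abstract_mentions={d: set(ts) for d, ts in obj["abstract_mentions"].items()},
            foreground_doc_ids=list(obj["foreground_doc_ids"]),
            module_members=list(obj["module_members"]),
            planted_term_id=obj["planted_term_id"],
        )


# ---------------------------------------------------------------------------
# Component generators
# ---------------------------------------------------------------------------

def target_symbol(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_lexicon(config: SyntheticConfig, rng: np.random.Generator) -> TargetLexicon:
    """Symbols G0001.. with 1..n synonym strings; digits keep every string
    case-sensitive under the default rule and outside the filler vocabulary."""
    entries = []
    for i in range(config.n_targets):
        symbol = target_symbol(i)
        n_syn = int(rng.integers(config.n_synonyms_min, config.n_synonyms_max + 1))
        strings = [symbol] + [f"{symbol.lower()}-syn{j + 1}" for j in range(n_syn - 1)]
        entries.append(LexiconEntry(
            target_id=symbol,
            name=f"synthetic gene {i + 1}",
            match_strings=tuple(strings),
            case_sensitive=tuple(True for _ in strings),
        ))
    return TargetLexicon(entries=entries)


def planted_targets(config: SyntheticConfig) -> list[PlantedTarget]:
    """The first ``n_planted`` lexicon targets, at the configured rates."""
    return [
        PlantedTarget(target_symbol(i), config.planted_foreground_prob,
                      config.planted_background_prob)
        for i in range(config.n_planted)
    ]


def sample_mention_sets(
    n_docs: int,
    target_ids: list[str],
    probs: np.ndarray,
    rng: np.random.Generator,
) -> list[set[str]]:
    """Independent per-document Bernoulli mentions at per-target probabilities."""
    draws = rng.random((n_docs, len(target_ids))) < probs
    return [{target_ids[j] for j in np.nonzero(row)[0]} for row in draws]


def mention_probabilities(
    config: SyntheticConfig, target_ids: list[str], foreground: bool
) -> np.ndarray:
    """Per-target mention probability vector for one document class."""
    planted = {p.target_id: p for p in planted_targets(config)}
    probs = np.full(len(target_ids), config.baseline_mention_prob)
    for j, t in enumerate(target_ids):
        if t in planted:
            probs[j] = (planted[t].foreground_prob if foreground
                        else planted[t].background_prob)
    return probs


def _document_text(
    mentioned: set[str],
    lexicon_by_id: dict[str, LexiconEntry],
    has_fulltext: bool,
    abstract_prob: float,
    rng: np.random.Generator,
) -> tuple[dict[str, str], set[str]]:
    """Assemble text units embedding one synonym per mention, plus filler.

    Returns (text_units, targets visible in title+abstract).  Without a
    fulltext unit every mention goes to the abstract; with one, each mention
    lands in the abstract with ``abstract_prob`` and otherwise only in the
    fulltext (documents' key content often never reaches the abstract).
    """
    abstract_tokens: list[str] = []
    fulltext_tokens: list[str] = []
    abstract_targets: set[str] = set()
    for t in sorted(mentioned):
        entry = lexicon_by_id[t]
        string = entry.match_strings[int(rng.integers(len(entry.match_strings)))]
        if not has_fulltext or rng.random() < abstract_prob:
            abstract_tokens.append(string)
            abstract_targets.add(t)
        else:
            fulltext_tokens.append(string)

    def weave(tokens: list[str], n_filler: int) -> str:
        words = list(tokens)
        for _ in range(n_filler):
            words.insert(int(rng.integers(len(words) + 1)),
                         _FILLER_VOCAB[int(rng.integers(len(_FILLER_VOCAB)))])
        return " ".join(words)

    units = {
        "title": weave([], 5),
        "abstract": weave(abstract_tokens, 12),
    }
    if has_fulltext:
        units["fulltext"] = weave(fulltext_tokens + abstract_tokens, 30)
    return units, abstract_targets


def generate_corpus(
    config: SyntheticConfig,
    lexicon: TargetLexicon,
    seed: int,
) -> tuple[Corpus, Corpus, GroundTruth]:
    """Generate the publication universe and its topic foreground.

    Every foreground document carries the excluded index terms; foreground
    documents are spread so each issue keeps at least as many non-indexed
    documents as indexed ones (so issue-matched sampling never starves).
    """
    rng = np.random.default_rng(seed)
    iss = config.issues
    issue_triples: list[tuple[str, str, str]] = []
    for j in range(iss.n_journals):
        for v in range(iss.volumes_per_journal):
            for i in range(iss.issues_per_volume):
                issue_triples.append((f"J{j + 1:02d}", f"V{v + 1}", f"I{i + 1}"))

    doc_issue: list[tuple[str, str, str]] = []
    for d in range(config.universe_docs):
        doc_issue.append(issue_triples[d % len(issue_triples)])

    # choose foreground docs, capping the per-issue load at half the issue size
    cap = iss.docs_per_issue // 2
    load: dict[tuple[str, str, str], int] = {}
    order = rng.permutation(config.universe_docs)
    fg_indices: set[int] = set()
    for d in order:
        if len(fg_indices) == config.foreground_docs:
            break
        triple = doc_issue[d]
        if load.get(triple, 0) < cap:
            fg_indices.add(int(d))
            load[triple] = load.get(triple, 0) + 1
    if len(fg_indices) < config.foreground_docs:
        raise CorpusValidationError("could not place all foreground documents")

    target_ids = [e.target_id for e in lexicon]
    lexicon_by_id = {e.target_id: e for e in lexicon}
    fg_probs = mention_probabilities(config, target_ids, foreground=True)
    bg_probs = mention_probabilities(config, target_ids, foreground=False)

    docs: list[DocumentRecord] = []
    mentions: dict[str, set[str]] = {}
    abstract_mentions: dict[str, set[str]] = {}
    fg_ids: list[str] = []
    for d in range(config.universe_docs):
        doc_id = f"D{d + 1:06d}"
        is_fg = d in fg_indices
        probs = fg_probs if is_fg else bg_probs
        mentioned = {
            target_ids[j] for j in np.nonzero(rng.random(len(target_ids)) < probs)[0]
        }
        has_fulltext = rng.random() < config.fulltext_fraction
        units, abstract_targets = _document_text(
            mentioned, lexicon_by_id, has_fulltext, config.abstract_mention_prob, rng
        )
        journal, volume, issue = doc_issue[d]
        mesh = frozenset(config.excluded_mesh) if is_fg else frozenset()
        docs.append(DocumentRecord(
            doc_id=doc_id, journal=journal, volume=volume, issue=issue,
            mesh_terms=mesh, text_units=units,
        ))
        mentions[doc_id] = mentioned
        abstract_mentions[doc_id] = abstract_targets
        if is_fg:
            fg_ids.append(doc_id)

    universe = Corpus(documents=docs, label="universe")
    foreground = Corpus(documents=[universe[i] for i in fg_ids], label="foreground")
    truth = GroundTruth(
        planted_targets=[p.target_id for p in planted_targets(config)],
        mentions=mentions,
        abstract_mentions=abstract_mentions,
        foreground_doc_ids=fg_ids,
        module_members=[],
        planted_term_id="",
    )
    return universe, foreground, truth


def generate_gold(
    config: SyntheticConfig,
    truth: GroundTruth,
    seed: int,
) -> GoldStandard:
    """Curated-links analogue: a sample of true foreground pairs plus a few
    pairs for extra-lexicon targets the tagger cannot know about (so recall
    stays below 1 and the merge step has work to do)."""
    rng = np.random.default_rng(seed)
    pairs: set[tuple[str, str]] = set()
    for doc_id in truth.foreground_doc_ids:
        for t in sorted(truth.mentions[doc_id]):
            if rng.random() < config.gold_pair_fraction:
                pairs.add((doc_id, t))
    extra = [f"GX{i + 1:03d}" for i in range(config.gold_missing_targets)]
    fg_ids = truth.foreground_doc_ids
    for t in extra:
        pairs.add((fg_ids[int(rng.integers(len(fg_ids)))], t))
    return GoldStandard(pairs=frozenset(pairs), provenance="synthetic curated links")


def generate_network(
    n_genes: int,
    p_background_edge: float,
    module_members: list[str],
    p_module_edge: float,
    seed: int,
    gene_ids: list[str] | None = None,
) -> InteractionNetwork:
    """Erdős–Rényi background with a planted module.

    Within-module pairs are connected with exactly ``p_module_edge``; every
    other pair with ``p_background_edge``.
    """
    if gene_ids is None:
        gene_ids = [target_symbol(i) for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise CorpusValidationError("gene_ids length must equal n_genes")
    unknown = set(module_members) - set(gene_ids)
    if unknown:
        raise CorpusValidationError(f"module members outside the gene universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    g = nx.fast_gnp_random_graph(
        n_genes, p_background_edge,
        seed=int(rng.integers(2**31 - 1)),
    )
    g = nx.relabel_nodes(g, {i: gene_ids[i] for i in range(n_genes)})
    module = sorted(module_members)
    # module pairs get exactly p_module_edge: clear, then redraw
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            u, v = module[i], module[j]
            if g.has_edge(u, v):
                g.remove_edge(u, v)
            if rng.random() < p_module_edge:
                g.add_edge(u, v)
    return InteractionNetwork(graph=g)


def generate_annotations(
    config: SyntheticConfig,
    gene_ids: list[str],
    planted_gene_list: list[str],
    seed: int,
) -> tuple[AnnotationCatalog, str]:
    """Random terms plus one planted term overlapping the planted targets.

    The planted term's gene set takes ``planted_overlap_fraction`` of its
    members from ``planted_gene_list`` and the rest at random.
    """
    rng = np.random.default_rng(seed)
    ann = config.annotations
    size_max = min(ann.term_size_max, len(gene_ids))  # small gene universes
    size_min = min(ann.term_size_min, size_max)
    catalog = AnnotationCatalog()
    for i in range(ann.n_terms):
        size = int(rng.integers(size_min, size_max + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        catalog.add(AnnotationTerm(
            term_id=f"T{i + 1:04d}",
            name=f"synthetic term {i + 1}",
            namespace="synthetic_process",
            genes=frozenset(gene_ids[j] for j in members),
        ))
    size = int(rng.integers(size_min, size_max + 1))
    n_from_planted = min(len(planted_gene_list), max(1, round(size * ann.planted_overlap_fraction)))
    chosen = list(rng.choice(len(planted_gene_list), size=n_from_planted, replace=False))
    members_set = {planted_gene_list[j] for j in chosen}
    others = [gid for gid in gene_ids if gid not in members_set]
    pad = rng.choice(len(others), size=size - len(members_set), replace=False)
    members_set |= {others[j] for j in pad}
    planted_id = "T_PLANTED"
    catalog.add(AnnotationTerm(
        term_id=planted_id, name="planted enriched term",
        namespace="synthetic_process", genes=frozenset(members_set),
    ))
    return catalog, planted_id


# ---------------------------------------------------------------------------
# One-call generation of a full input bundle
# ---------------------------------------------------------------------------

@dataclass
class Manifest:
    """Paths of every emitted file."""

    universe: Path
    foreground: Path
    lexicon: Path
    gold: Path
    network: Path
    annotations: Path
    ground_truth: Path

    def as_dict(self) -> dict[str, str]:
        return {k: str(v) for k, v in dataclasses.asdict(self).items()}


def generate_all(config: SyntheticConfig, out_dir: str | Path) -> tuple[Manifest, GroundTruth]:
    """Emit every pipeline input under ``out_dir``; byte-identical per seed.

    Stage seeds are derived from ``config.seed`` by fixed offsets so the
    components are independent but jointly reproducible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in zip(
        ("lexicon", "corpus", "gold", "network", "annotations"),
        root_rng.integers(0, 2**31 - 1, size=5),
    )}

    lexicon = generate_lexicon(config, np.random.default_rng(seeds["lexicon"]))
    universe, foreground, truth = generate_corpus(config, lexicon, seeds["corpus"])
    gold = generate_gold(config, truth, seeds["gold"])

    net_cfg = config.network
    module = [p.target_id for p in planted_targets(config)]
    if net_cfg.module_size > len(module):
        extra_pool = [t for t in lexicon.target_ids if t not in module]
        rng = np.random.default_rng(seeds["network"] + 1)
        pad = rng.choice(len(extra_pool), size=net_cfg.module_size - len(module),
                         replace=False)
        module = module + [extra_pool[j] for j in pad]
    n_genes = max(net_cfg.n_genes, config.n_targets)
    gene_ids = [target_symbol(i) for i in range(n_genes)]
    network = generate_network(
        n_genes, net_cfg.p_background_edge, module, net_cfg.p_module_edge,
        seeds["network"], gene_ids=gene_ids,
    )
    catalog, planted_term = generate_annotations(
        config, lexicon.target_ids, module, seeds["annotations"]
    )
    truth.module_members = sorted(module)
    truth.planted_term_id = planted_term

    manifest = Manifest(
        universe=out_dir / "universe.jsonl",
        foreground=out_dir / "foreground.jsonl",
        lexicon=out_dir / "lexicon.tsv",
        gold=out_dir / "gold.tsv",
        network=out_dir / "network.tsv",
        annotations=out_dir / "annotations.gmt",
        ground_truth=out_dir / "ground_truth.json",
    )
    write_corpus(universe, manifest.universe)
    write_corpus(foreground, manifest.foreground)
    write_lexicon(lexicon, manifest.lexicon)
    write_gold(gold, manifest.gold)
    write_edge_list(network, manifest.network)
    write_gene_sets(catalog, manifest.annotations)
    manifest.ground_truth.write_text(truth.to_json(), encoding="utf-8")
    return manifest, truth
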