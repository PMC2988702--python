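"""End-to-end orchestration: simulate → tag → backgrounds → screen → report.

A single :class:`PipelineConfig` (loadable from YAML) drives the run; every
stage is also callable on its own through the library API or the CLI.  The
run produces a :class:`RunReport` holding per-stage summaries, and
:func:`write_report` emits the tabular outputs (target frequencies, the
ranked over-represented target table, the network null comparison, and the
enrichment tables) plus a machine-readable JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .backgrounds import (
    BackgroundSpec,
    background_homogeneity_test,
    check_background_set,
    overlap_counts,
    sample_backgrounds,
)
from .corpus import Corpus, read_corpus, read_gold, read_lexicon, write_corpus
from .enrich import enrich, read_gene_sets
from .network import (
    compare_to_null,
    read_edge_list,
    sample_null_distribution,
    target_network_stats,
)
from .overrep import consensus_select, overrep_test, selected_table, target_frequencies
from .simulate import SyntheticConfig, generate_all
from .tagging import (
    CompiledLexicon,
    DocumentTargetMatrix,
    evaluate_against_gold,
    merge_curated_targets,
    tag_corpus,
    write_matrix,
)

logger = logging.getLogger(__name__)

FULL_SCOPE = frozenset(("title", "abstract", "fulltext"))
ABSTRACT_SCOPE = frozenset(("title", "abstract"))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _synthetic_config_from_dict(obj: dict) -> SyntheticConfig:
    from .simulate import AnnotationConfig, IssueStructure, NetworkConfig

    obj = dict(obj)
    nested = {"issues": IssueStructure, "network": NetworkConfig,
              "annotations": AnnotationConfig}
    for key, cls in nested.items():
        if key in obj and isinstance(obj[key], dict):
            obj[key] = cls(**obj[key])
    if "excluded_mesh" in obj:
        obj["excluded_mesh"] = tuple(obj["excluded_mesh"])
    return SyntheticConfig(**obj)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    out_dir: Path
    universe_path: Path | None = None
    foreground_path: Path | None = None
    lexicon_path: Path | None = None
    gold_path: Path | None = None
    network_path: Path | None = None
    annotations_path: Path | None = None
    simulate: SyntheticConfig | None = None

    excluded_mesh: tuple[str, ...] = ("Topic A", "Topic B")
    n_background_sets: int = 3
    background_fallback: str = "skip"
    scope: str = "fulltext"  # "fulltext" or "abstract"
    alpha_raw: float = 0.05
    alpha_bh: float = 0.05
    min_bh_sets: int = 2
    require_all_raw: bool = True
    ppi_iterations: int = 100
    seed: int = 0

    def text_scope(self) -> frozenset[str]:
        if self.scope == "fulltext":
            return FULL_SCOPE
        if self.scope == "abstract":
            return ABSTRACT_SCOPE
        raise PipelineError(f"config: unknown scope {self.scope!r}")

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived from the run seed by fixed offsets."""
        base = self.seed
        return {
            "simulate": base,
            "backgrounds": base + 1000,
            "ppi": base + 2000,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = obj.pop("simulate", None)
        cfg = cls(
            out_dir=Path(obj.pop("out_dir", "litdisc_run")),
            **{
                k: (Path(v) if k.endswith("_path") and v is not None else
                    tuple(v) if k == "excluded_mesh" else v)
                for k, v in obj.items()
            },
        )
        if sim is not None:
            cfg.simulate = _synthetic_config_from_dict(sim) if isinstance(sim, dict) \
                else SyntheticConfig()
        return cfg


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    version: str
    config: dict
    stage_seeds: dict[str, int]
    corpus_summary: dict = field(default_factory=dict)
    tagging_summary: dict = field(default_factory=dict)
    background_summary: dict = field(default_factory=dict)
    homogeneity_summary: dict = field(default_factory=dict)
    overrep_summary: dict = field(default_factory=dict)
    evaluation_summary: dict = field(default_factory=dict)
    ppi_summary: dict = field(default_factory=dict)
    enrichment_summary: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def body(self) -> dict:
        """The JSON-serialisable report body (tables rendered as records)."""
        return {
            "version": self.version,
            "config": self.config,
            "stage_seeds": self.stage_seeds,
            "corpus": self.corpus_summary,
            "tagging": self.tagging_summary,
            "backgrounds": self.background_summary,
            "homogeneity": self.homogeneity_summary,
            "overrepresentation": self.overrep_summary,
            "evaluation": self.evaluation_summary,
            "ppi": self.ppi_summary,
            "enrichment": self.enrichment_summary,
            "tables": {
                name: df.reset_index().to_dict(orient="records")
                for name, df in sorted(self.tables.items())
            },
        }


def _config_echo(config: PipelineConfig) -> dict:
    obj = dataclasses.asdict(config)
    for k, v in obj.items():
        if isinstance(v, Path):
            obj[k] = str(v)
    return obj


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and return the run report.

    Stages: (0) optional simulation of all inputs, (1) foreground tagging,
    (2) background sampling + tagging + homogeneity check, (3) per-background
    exact tests and consensus selection, (4) gold-standard evaluation and
    curated-target merge, (5) network connectivity null, (6) term enrichment
    of the selected targets.  Reruns with identical config and seed produce
    an identical report body.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    report = RunReport(version=__version__, config=_config_echo(config),
                       stage_seeds=seeds)
    stage = "simulate"
    try:
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            manifest, _truth = generate_all(sim_cfg, out_dir / "inputs")
            config.universe_path = manifest.universe
            config.foreground_path = manifest.foreground
            config.lexicon_path = manifest.lexicon
            config.gold_path = manifest.gold
            config.network_path = manifest.network
            config.annotations_path = manifest.annotations
            config.excluded_mesh = tuple(sim_cfg.excluded_mesh)
            report.config = _config_echo(config)

        stage = "load"
        if config.foreground_path is None or config.lexicon_path is None:
            raise PipelineError("config must provide (or simulate) a foreground corpus and lexicon")
        foreground = read_corpus(config.foreground_path, label="foreground")
        lexicon = read_lexicon(config.lexicon_path)
        universe = (read_corpus(config.universe_path, label="universe")
                    if config.universe_path else None)
        report.corpus_summary = {
            "foreground_docs": len(foreground),
            "universe_docs": len(universe) if universe else None,
            "lexicon_targets": len(lexicon),
            "scope": config.scope,
        }

        stage = "tag"
        compiled = CompiledLexicon(lexicon)
        scope = config.text_scope()
        fg_matrix = tag_corpus(foreground, compiled, scope)
        write_matrix(fg_matrix, out_dir / "foreground_matrix.tsv")
        report.tagging_summary = {
            "identified_targets": int(fg_matrix.n_targets),
            "collisions": len(compiled.collisions),
        }
        freqs = target_frequencies(fg_matrix)
        freq_table = pd.DataFrame(
            [{"target_id": f.target_id, "doc_count": f.doc_count,
              "frequency": f.frequency} for f in freqs]
        ).sort_values(["doc_count", "target_id"], ascending=[False, True]).set_index("target_id")
        report.tables["target_frequencies"] = freq_table

        stage = "backgrounds"
        consensus = None
        if universe is not None:
            spec = BackgroundSpec(
                excluded_mesh=frozenset(config.excluded_mesh),
                n_sets=config.n_background_sets,
                seeds=tuple(seeds["backgrounds"] + i for i in range(config.n_background_sets)),
                fallback=config.background_fallback,
            )
            bg_sets = sample_backgrounds(universe, foreground, spec)
            for bg in bg_sets:
                check_background_set(bg, universe, foreground, spec)
                write_corpus(bg.corpus, out_dir / f"background_seed{bg.seed}.jsonl")
                with (out_dir / f"background_seed{bg.seed}_matching.tsv").open(
                    "w", encoding="utf-8"
                ) as fh:
                    for fg_id, bg_id in sorted(bg.matching.items()):
                        fh.write(f"{fg_id}\t{bg_id}\n")
            bg_matrices = [tag_corpus(bg.corpus, compiled, scope) for bg in bg_sets]
            report.background_summary = {
                "n_sets": len(bg_sets),
                "sizes": [len(bg.corpus) for bg in bg_sets],
                "skipped": [len(bg.skipped) for bg in bg_sets],
                "document_overlap": {
                    str(m): c for m, c in overlap_counts(
                        [set(bg.corpus.doc_ids) for bg in bg_sets]
                    ).items()
                },
            }

            stage = "homogeneity"
            if len(bg_matrices) >= 2:
                hom = background_homogeneity_test(bg_matrices, alpha=config.alpha_bh)
                report.homogeneity_summary = {
                    "tests": int(len(hom)),
                    "significant_targets": int(
                        hom.loc[hom["significant"], "target_id"].nunique()
                    ),
                }
                report.tables["background_homogeneity"] = hom.set_index(
                    ["target_id", "set_a", "set_b"]
                )

            stage = "overrepresentation"
            # one shared target universe across comparisons
            all_targets = sorted(
                set(fg_matrix.target_ids).union(*(set(m.target_ids) for m in bg_matrices))
            )
            def widen(m: DocumentTargetMatrix) -> DocumentTargetMatrix:
                mentions = {
                    d: m.targets_of(d) for d in m.doc_ids
                }
                return DocumentTargetMatrix.from_mentions(
                    m.doc_ids, mentions, all_targets, m.corpus_label
                )

            fg_wide = widen(fg_matrix)
            comparisons = [overrep_test(fg_wide, widen(m)) for m in bg_matrices]
            consensus = consensus_select(
                comparisons,
                alpha_raw=config.alpha_raw,
                alpha_bh=config.alpha_bh,
                min_bh_sets=config.min_bh_sets,
                require_all_raw=config.require_all_raw,
            )
            sel = selected_table(consensus)
            report.overrep_summary = {
                "tested_targets": int(len(consensus)),
                "selected_targets": int(consensus["selected"].sum()),
                "top_selected": sel.index.tolist()[:10],
            }
            report.tables["overrepresented_targets"] = consensus

        stage = "evaluate"
        identified = fg_matrix.identified_targets()
        working_targets = set(identified)
        if config.gold_path is not None:
            gold = read_gold(config.gold_path)
            metrics = evaluate_against_gold(fg_matrix, gold, level="target_set")
            merged, counts = merge_curated_targets(identified, gold.target_ids)
            working_targets = merged
            report.evaluation_summary = {
                "recall": metrics.recall,
                "recall_percent": round(100 * metrics.recall),
                "true_positives": metrics.true_positives,
                "false_negatives": metrics.false_negatives,
                "n_identified": counts.n_identified,
                "n_gold": counts.n_gold,
                "n_overlap": counts.n_overlap,
                "n_merged": counts.n_merged,
            }

        stage = "ppi"
        if config.network_path is not None:
            network = read_edge_list(config.network_path)
            gene_universe = network.nodes | working_targets
            observed = target_network_stats(network, working_targets)
            samples = sample_null_distribution(
                network, gene_universe, len(working_targets),
                n_iterations=config.ppi_iterations, seed=seeds["ppi"],
            )
            comparison = compare_to_null(observed, samples, seed=seeds["ppi"])
            report.ppi_summary = {
                "target_set_size": len(working_targets),
                "gene_universe": len(gene_universe),
                "n_iterations": config.ppi_iterations,
                "z": {k: float(v) for k, v in comparison.z.items()},
                "empirical_p": {k: float(v) for k, v in comparison.empirical_p.items()},
            }
            report.tables["ppi_null_comparison"] = comparison.to_frame()
            samples.to_csv(out_dir / "ppi_null_samples.tsv", sep="\t", index=False)

        stage = "enrich"
        if config.annotations_path is not None:
            catalog = read_gene_sets(config.annotations_path)
            enrich_universe = set(lexicon.target_ids) | working_targets
            enrich_targets = (
                set(selected_table(consensus).index) if consensus is not None
                and bool(consensus["selected"].any())
                else working_targets
            )
            results = enrich(enrich_targets, catalog, enrich_universe)
            report.enrichment_summary = {
                "n_terms_tested": int(len(results)),
                "n_significant": int((results["p_bh"] < config.alpha_bh).sum())
                if not results.empty else 0,
                "top_terms": results["term_id"].tolist()[:5] if not results.empty else [],
            }
            report.tables["enrichment"] = (
                results.set_index("term_id") if not results.empty else results
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, str]:
    """Emit TSV tables, a JSON report and a plain-text summary; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, df in sorted(report.tables.items()):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        manifest[name] = str(path)

    json_path = out_dir / "report.json"
    json_path.write_text(
        json.dumps(report.body(), indent=1, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    manifest["report_json"] = str(json_path)

    lines = [f"litdisc {report.version} run summary", ""]
    for title, summary in (
        ("Corpus", report.corpus_summary),
        ("Tagging", report.tagging_summary),
        ("Backgrounds", report.background_summary),
        ("Background homogeneity", report.homogeneity_summary),
        ("Over-representation", report.overrep_summary),
        ("Gold-standard evaluation", report.evaluation_summary),
        ("Network null", report.ppi_summary),
        ("Enrichment", report.enrichment_summary),
    ):
        if summary:
            lines.append(f"[{title}]")
            for k, v in summary.items():
                lines.append(f"  {k}: {v}")
            lines.append("")
    txt_path = out_dir / "summary.txt"
    txt_path.write_text("\n".join(lines), encoding="utf-8")
    manifest["summary"] = str(txt_path)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest["manifest"] = str(manifest_path)
    return manifest
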