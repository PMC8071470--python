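"""End-to-end orchestration: data -> functionome -> calls -> reports.

A run executes the full analysis over either user-supplied files
(expression TSV + labels TSV + GMT [+ OBO, + pathway GMT]) or a seeded
synthetic cohort, and writes the tabular reports to an output directory:
a functionome matrix, set- and gene-level test tables, per-group GSR
summaries and histograms, a ranked ontology-cluster table (and, with
subtype labels, per-subtype tables plus the cross-group common-term
table), a classification report, a ranked canonical-pathway table, and
linked representative genes per category.  A manifest records the seed and
all stage counts so the silent filters (set retention, gene intersection)
stay auditable.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .classify import cv_classify
from .clustering import (
    build_clusters,
    clusters_to_frame,
    common_top_terms,
    load_term_categories,
    rank_clusters,
)
from .data_io import (
    ExpressionMatrix,
    GeneSetCollection,
    read_expression_table,
    read_gmt,
    read_labels,
    read_obo,
    write_expression_table,
    write_gmt,
    write_labels,
)
from .gsr import build_functionome, corrected_group_mean
from .linkage import rank_repetition, repetitions_to_frame
from .stats import (
    SetTestResult,
    call_degs,
    call_dysregulated,
    results_to_frame,
    summarize_histogram,
)
from .synthetic import SyntheticConfig, generate_cohort, generate_collection, generate_ontology

__all__ = ["RunConfig", "run_pipeline", "pathway_rank", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` or the (expression, labels, gmt) file trio
    must be provided.  ``pathway_gmt`` triggers the additional canonical-
    pathway ranking; ``obo`` supplies the ontology for clustering (the
    synthetic route generates one).
    """

    out_dir: str | Path = "results/run"
    expression: str | Path | None = None
    labels: str | Path | None = None
    gmt: str | Path | None = None
    obo: str | Path | None = None
    pathway_gmt: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    alpha: float = 0.05
    n_folds: int = 5
    n_repeats: int = 10
    n_bins: int = 50
    top_k: int = 50
    seed: int = 0
    leave_one_out: bool = False
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        real = all(x is not None for x in (self.expression, self.labels, self.gmt))
        if self.synthetic is None and not real:
            raise ValueError("provide either synthetic config or expression+labels+gmt paths")
        if self.synthetic is not None and real:
            raise ValueError("synthetic config and real input files are mutually exclusive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML file.

        A ``synthetic:`` mapping becomes a ``SyntheticConfig``; remaining
        keys map onto the dataclass fields.
        """
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        return cls(**raw)


def pathway_rank(results: list[SetTestResult], top_n: int | None = None) -> pd.DataFrame:
    """Rank pathway-collection test results by ascending raw p (ties by id)."""
    if not results:
        raise ValueError("no pathway results to rank")
    ordered = sorted(results, key=lambda r: (r.p_raw, r.set_id))
    if top_n is not None:
        ordered = ordered[:top_n]
    df = results_to_frame(ordered)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("data_io")
def _load_inputs(config: RunConfig, out: Path):
    if config.synthetic is not None:
        coll = generate_collection(config.synthetic)
        matrix, truth = generate_cohort(config.synthetic, coll)
        graph = generate_ontology(coll, depth=2, seed=config.synthetic.seed)
        data_dir = out / "data"
        data_dir.mkdir(parents=True, exist_ok=True)
        write_expression_table(matrix, data_dir / "expression.tsv")
        write_labels(matrix, data_dir / "labels.tsv")
        write_gmt(coll, data_dir / "gene_sets.gmt")
        truth.to_json(data_dir / "truth.json")
        return matrix, coll, graph, None
    groups, subtypes, platforms = read_labels(config.labels)
    matrix = read_expression_table(config.expression, groups, subtypes, platforms)
    coll = read_gmt(config.gmt)
    graph = read_obo(config.obo) if config.obo else nx.DiGraph()
    pathway_coll = read_gmt(config.pathway_gmt, source_tag="canonical_pathway") if config.pathway_gmt else None
    return matrix, coll, graph, pathway_coll


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run manifest.

    Any stage error aborts the run, removes partial outputs, and raises a
    ``PipelineError`` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "outputs": {},
        "counts": {},
    }

    def emit(key: str, name: str, df: pd.DataFrame, index=False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        manifest["outputs"][key] = str(path)

    try:
        matrix, coll, graph, pathway_coll = _load_inputs(config, out)
        manifest["counts"]["genes"] = len(matrix.gene_ids)
        manifest["counts"]["samples"] = len(matrix.sample_ids)
        manifest["counts"]["sets_raw"] = len(coll)

        functionome = _stage("gsr_core")(build_functionome)(
            matrix, coll, leave_one_out=config.leave_one_out
        )
        manifest["counts"]["sets_retained"] = len(functionome.set_ids)
        manifest["counts"]["sets_skipped"] = len(functionome.skipped)
        functionome.to_tsv(out / "functionome.tsv")
        manifest["outputs"]["functionome"] = str(out / "functionome.tsv")
        emit("skip_log", "skip_log.tsv", functionome.skipped)

        stats_stage = _stage("dysregulation_stats")
        set_results = stats_stage(call_dysregulated)(
            functionome, matrix.groups, alpha=config.alpha
        )
        emit("set_tests", "set_tests.tsv", results_to_frame(set_results))
        n_sig = sum(r.significant for r in set_results)
        manifest["counts"]["significant_sets"] = int(n_sig)

        deg_results = stats_stage(call_degs)(matrix, alpha=config.alpha)
        emit("gene_tests", "gene_tests.tsv", results_to_frame(deg_results))
        manifest["counts"]["significant_genes"] = int(
            sum(r.significant for r in deg_results)
        )

        hist = stats_stage(summarize_histogram)(
            functionome, matrix.groups, n_bins=config.n_bins
        )
        emit("histogram", "gsr_histogram.tsv", hist.to_frame())
        case_mean, case_sd = corrected_group_mean(functionome, matrix.case_ids)
        ctrl_mean, ctrl_sd = corrected_group_mean(functionome, matrix.control_ids)
        emit(
            "group_summary",
            "group_summary.tsv",
            pd.DataFrame(
                [
                    {"group": "case", "n": len(matrix.case_ids), "gsr_mean": case_mean, "gsr_sd": case_sd},
                    {"group": "control", "n": len(matrix.control_ids), "gsr_mean": ctrl_mean, "gsr_sd": ctrl_sd},
                ]
            ),
        )

        cluster_stage = _stage("go_clustering")
        significant = [r for r in set_results if r.significant]
        names = {gs.set_id: gs.name for gs in coll}
        if significant:
            clusters = cluster_stage(build_clusters)(significant, graph)
            emit("clusters", "clusters.tsv", clusters_to_frame(clusters, names))
            manifest["counts"]["clusters"] = len(clusters)
        else:
            manifest["counts"]["clusters"] = 0

        subtype_heads: dict[str, list[str]] = {}
        if matrix.subtypes is not None:
            case_subtypes = matrix.subtypes[matrix.groups == "case"].dropna()
            for sub in sorted(case_subtypes.unique()):
                keep = list(case_subtypes.index[case_subtypes == sub]) + matrix.control_ids
                sub_f = type(functionome)(
                    gsr=functionome.gsr.loc[keep], skipped=functionome.skipped
                )
                sub_results = stats_stage(call_dysregulated)(
                    sub_f, matrix.groups.reindex(keep), alpha=config.alpha
                )
                sub_sig = [r for r in sub_results if r.significant]
                if not sub_sig:
                    continue
                ranked = cluster_stage(rank_clusters)(
                    cluster_stage(build_clusters)(sub_sig, graph)
                )
                emit(
                    f"clusters_{sub}",
                    f"clusters_{sub}.tsv",
                    clusters_to_frame([c for c in ranked], names),
                )
                subtype_heads[sub] = [c.head_term for c in ranked]
        if len(subtype_heads) >= 2:
            common = cluster_stage(common_top_terms)(subtype_heads, k=config.top_k)
            emit("common_terms", "common_terms.tsv", common)
            manifest["counts"]["common_terms"] = len(common)

        _stage("classification")(_classify_and_emit)(
            functionome, matrix, config, emit
        )

        if pathway_coll is not None:
            pw_f = _stage("gsr_core")(build_functionome)(
                matrix, pathway_coll, leave_one_out=config.leave_one_out
            )
            pw_results = stats_stage(call_dysregulated)(
                pw_f, matrix.groups, alpha=config.alpha
            )
            emit("pathway_rank", "pathway_rank.tsv", pathway_rank(pw_results))

        link_stage = _stage("gene_linkage")
        category_map = config.category_map or load_term_categories()
        categories: dict[str, list[str]] = {}
        for term, cat in category_map.items():
            if term in coll:
                categories.setdefault(cat, []).append(term)
        link_frames = []
        for cat, terms in sorted(categories.items()):
            reps = link_stage(rank_repetition)(terms, coll, deg_results)
            link_frames.append(repetitions_to_frame(reps, category=cat))
        if link_frames:
            emit("linked_genes", "linked_genes.tsv", pd.concat(link_frames, ignore_index=True))

        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise


def _classify_and_emit(functionome, matrix: ExpressionMatrix, config: RunConfig, emit) -> None:
    frames = [
        cv_classify(
            functionome,
            matrix.groups,
            n_folds=config.n_folds,
            n_repeats=config.n_repeats,
            seed=config.seed,
            group="all_cases",
        ).to_frame()
    ]
    if matrix.subtypes is not None:
        case_subtypes = matrix.subtypes[matrix.groups == "case"].dropna()
        for sub in sorted(case_subtypes.unique()):
            keep = list(case_subtypes.index[case_subtypes == sub]) + matrix.control_ids
            if (case_subtypes == sub).sum() < config.n_folds:
                continue
            sub_f = type(functionome)(
                gsr=functionome.gsr.loc[keep], skipped=functionome.skipped
            )
            frames.append(
                cv_classify(
                    sub_f,
                    matrix.groups.reindex(keep),
                    n_folds=config.n_folds,
                    n_repeats=config.n_repeats,
                    seed=config.seed,
                    group=sub,
                ).to_frame()
            )
    emit("classification", "classification.tsv", pd.concat(frames, ignore_index=True))
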