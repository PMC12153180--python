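"""Pipeline orchestration: stage ordering, input validation, artifact
directory layout and logging.

Stages and their products (all tabular outputs carry the version/config
header line):

- ``simulate``  -> sim_families.faa, sim_truth.tsv
- ``benchmark`` -> benchmark_scores.tsv, benchmark_summary.tsv
- ``search``    -> chains.tsv, retrieved.faa
- ``ssn``       -> ssn_edges.tsv, clusters.tsv, cluster_stats.tsv,
                   divergent_clusters.tsv, meta_network.tsv
- ``annotate``  -> labels.tsv
- ``biogeo``    -> enrichment.tsv, enrichment_station.tsv,
                   enrichment_layer.tsv, fold_change_matrix.csv

Stages run in dependency order regardless of the order given in the config;
inputs of every requested stage are validated before any stage runs.
Re-running with an identical config and seed reproduces identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import annotate as ann
from . import biogeo as bg
from . import io as dio
from . import simbench as sb
from . import ssncluster as ssn
from .itersearch import iterative_search
from .pairalign import Thresholds, protein_scheme, search_all
from .records import SequenceRecord

logger = logging.getLogger("divmine.pipeline")

STAGE_ORDER = ["simulate", "benchmark", "search", "ssn", "annotate", "biogeo"]


def _thresholds(config: dict) -> Thresholds:
    t = config.get("thresholds", {})
    return Thresholds(
        max_evalue=float(t.get("max_evalue", 1e-5)),
        min_identity_pct=float(t.get("min_identity_pct", 30.0)),
        min_mutual_coverage=float(t.get("min_mutual_coverage", 0.8)),
    )


def _require(config: dict, stage: str, key: str) -> Path:
    section = config.get(stage, {})
    if key not in section:
        raise ValueError(f"stage {stage!r} requires config key {stage}.{key}")
    path = Path(section[key])
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: input {path} does not exist")
    return path


def validate_config(config: dict) -> List[str]:
    """Check stage names and the existence of every required input; returns
    the requested stages in dependency order."""
    stages = config.get("stages", [])
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in stages]
    for stage in ordered:
        if stage == "search":
            _require(config, "search", "seeds_fasta")
            _require(config, "search", "env_fasta")
        elif stage == "annotate":
            _require(config, "annotate", "reference_hits")
        elif stage == "biogeo":
            _require(config, "biogeo", "metadata")
        elif stage == "ssn" and "search" not in stages:
            _require(config, "search", "seeds_fasta")
            _require(config, "search", "env_fasta")
    if "biogeo" in ordered and "annotate" not in ordered:
        raise ValueError("stage 'biogeo' requires stage 'annotate' (divergence labels)")
    return ordered


def _design_from_config(section: dict) -> List[sb.SimFamily]:
    return sb.generate_design(
        n_leaves=int(section.get("n_leaves", sb.SCALED_N_LEAVES)),
        factors=tuple(float(f) for f in section.get("factors", sb.SCALED_FACTORS)),
        replicates=int(section.get("replicates", sb.SCALED_REPLICATES)),
        base_branch_length=(
            float(section["branch_length"]) if "branch_length" in section else None
        ),
        root_length=int(section.get("root_length", sb.SCALED_ROOT_LENGTH)),
    )


def run_pipeline(config: dict) -> Path:
    """Run the configured stages; returns the artifact directory."""
    outdir = Path(config.get("outdir", "divmine_out"))
    ordered = validate_config(config)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.setup_logging(config.get("log_level", "INFO"), outdir / "pipeline.log")
    master_seed = int(config.get("seed", 0))
    scheme = protein_scheme()
    thresholds = _thresholds(config)
    backend = config.get("backend", "builtin")
    ctx: Dict[str, object] = {}

    for stage in ordered:
        logger.info("stage %s: start", stage)
        section = config.get(stage, {})

        if stage == "simulate":
            families = _design_from_config(section)
            sb.realize_all(families, model=section.get("model", "lg"),
                           master_seed=dio.derive_seed(master_seed, "simulate"))
            dio.write_fasta(sb.pool_records(families), outdir / "sim_families.faa")
            dio._write_tsv(sb.truth_frame(families), outdir / "sim_truth.tsv", config)
            ctx["families"] = families

        elif stage == "benchmark":
            families = ctx.get("families")
            if families is None:
                families = _design_from_config(section)
                sb.realize_all(families, model=section.get("model", "lg"),
                               master_seed=dio.derive_seed(master_seed, "simulate"))
            scores, _ = sb.run_benchmark(
                families, scheme, thresholds, backend=section.get("backend", backend)
            )
            dio._write_tsv(sb.scores_frame(scores), outdir / "benchmark_scores.tsv", config)
            dio._write_tsv(sb.summarize_scores(scores), outdir / "benchmark_summary.tsv", config)

        elif stage == "search":
            seeds = dio.read_fasta(_require(config, "search", "seeds_fasta"), source="seed")
            env = dio.read_fasta(_require(config, "search", "env_fasta"))
            family_id = section.get("family_id", "FAM0001")
            retrieved = iterative_search(
                seeds, env, scheme, thresholds, backend=backend, family_id=family_id
            )
            dio.write_chains(retrieved, outdir / "chains.tsv", family_id, config)
            env_by_id = {e.id: e for e in env}
            dio.write_fasta([env_by_id[i] for i in sorted(retrieved)], outdir / "retrieved.faa")
            ctx["seeds"], ctx["retrieved_records"] = seeds, [env_by_id[i] for i in sorted(retrieved)]

        elif stage == "annotate":
            ref_hits = dio.read_hit_table(_require(config, "annotate", "reference_hits"))
            ids = [r.id for r in ctx.get("retrieved_records", [])] or sorted(set(ref_hits["qseqid"]))
            labels = ann.best_reference_similarity(ref_hits, sequence_ids=ids)
            ann.label_divergent(labels, float(section.get("divergence_threshold", 34.9)))
            dio._write_tsv(ann.labels_to_frame(labels), outdir / "labels.tsv", config)
            ctx["labels"] = labels

        elif stage == "ssn":
            seeds = ctx.get("seeds") or dio.read_fasta(
                _require(config, "search", "seeds_fasta"), source="seed"
            )
            retrieved = ctx.get("retrieved_records")
            if retrieved is None:
                retrieved = dio.read_fasta(outdir / "retrieved.faa")
            members = list(seeds) + list(retrieved)
            hits = search_all(members, members, scheme, thresholds, backend=backend)
            dio.write_hit_table(hits, outdir / "ssn_hits.tsv", config)
            graph = ssn.build_ssn(members, hits, thresholds.max_evalue,
                                  thresholds.min_identity_pct, thresholds.min_mutual_coverage)
            edges = pd.DataFrame(
                [{"node_a": a, "node_b": b, "weight": d["weight"]}
                 for a, b, d in sorted(graph.edges(data=True))],
                columns=["node_a", "node_b", "weight"],
            )
            dio._write_tsv(edges, outdir / "ssn_edges.tsv", config)
            clusters = ssn.partition_louvain(graph, seed=dio.derive_seed(master_seed, "ssn"))
            source_of = {m.id: m.source for m in members}
            labels = ctx.get("labels", {})
            sim_of = {k: v.best_identity for k, v in labels.items()} if labels else None
            for c in clusters:
                ssn.cluster_statistics(c, source_of, sim_of)
            family_id = config.get("search", {}).get("family_id", "FAM0001")
            dio.write_clusters(ssn.clusters_to_frame(clusters, family_id), outdir / "clusters.tsv", config)
            dio._write_tsv(ssn.cluster_stats_frame(clusters), outdir / "cluster_stats.tsv", config)
            divergent = ssn.select_divergent_clusters(
                clusters,
                min_size=int(section.get("min_size", 30)),
                min_env_fraction=float(section.get("min_env_fraction", 0.9)),
                max_mean_similarity=float(section.get("max_mean_similarity", 40.0)),
            )
            dio._write_tsv(ssn.cluster_stats_frame(divergent), outdir / "divergent_clusters.tsv", config)
            meta = ssn.condense_meta_network(graph, clusters)
            meta_df = pd.DataFrame(
                [{"cluster_a": a, "cluster_b": b, "weight": round(d["weight"], 6)}
                 for a, b, d in sorted(meta.edges(data=True))],
                columns=["cluster_a", "cluster_b", "weight"],
            )
            dio._write_tsv(meta_df, outdir / "meta_network.tsv", config)
            ctx["clusters"] = clusters

        elif stage == "biogeo":
            metadata = dio.read_metadata(_require(config, "biogeo", "metadata"))
            labels = ctx.get("labels")
            if labels is None:
                raise ValueError("biogeo requires the annotate stage (divergence labels)")
            div_of = {k: bool(v.divergent) for k, v in labels.items()}
            counts = bg.tabulate_samples(sorted(div_of), div_of, metadata)
            gf = bg.global_divergent_fraction(div_of)
            enr = bg.binomial_enrichment(counts, gf)
            dio._write_tsv(enr, outdir / "enrichment.tsv", config)
            for margin, fname in (("station", "enrichment_station.tsv"),
                                  ("depth_layer", "enrichment_layer.tsv")):
                mc = bg.margin_counts(counts, margin)
                dio._write_tsv(bg.binomial_enrichment(mc, gf), outdir / fname, config)
            with open(outdir / "fold_change_matrix.csv", "w") as fh:
                fh.write(dio.output_header(config) + "\n")
                bg.fold_change_matrix(enr).to_csv(fh)

        logger.info("stage %s: done", stage)
    return outdir
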