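"""End-to-end orchestration: load inputs, run the four inference stages,
build the networks, persist every result with a run log.

Two entry styles:

* :func:`run_pipeline` takes a :class:`PipelineConfig` with file paths
  (optionally loaded from YAML) and writes all outputs to a directory.
* :func:`run_from_objects` takes already-loaded artifacts and returns the
  in-memory results — the route the synthetic-scenario experiments use.

A "precomputed-list mode" accepts externally supplied list 1 / list 2
files, bypassing stages 1–2 so published candidate lists can exercise the
downstream stages without the original enrichment libraries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import io as cio
from .enrichment import EnrichmentTable
from .io import GeneList, GeneSetLibrary, InteractionTable, TFCatalog
from .network import (
    TFNetwork,
    add_ppi_overlay,
    build_regulatory_network,
    rank_hubs,
    write_edge_list,
    write_graphml,
    write_node_stats,
)
from .pipeline import (
    CoreTFReport,
    SharedPathwayResult,
    call_core_tfs,
    select_tfs,
    shared_enrichments,
    tf_target_enrichment,
)

logger = logging.getLogger("coretf")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_from_objects", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """File-level configuration for one run."""

    selected_genes: Optional[str] = None
    tf_catalog: Optional[str] = None
    tf_catalog_aliases: Optional[str] = None
    tf_targets: Optional[str] = None
    pathway_libraries: tuple[str, ...] = ()
    interactions: Optional[str] = None
    background_universe: Optional[str] = None
    # precomputed-list mode
    list1: Optional[str] = None
    list2: Optional[str] = None

    background_size: int = 22000
    threshold: float = 0.01
    parse_tf_names: bool = True
    tf_name_dialect: str = "whitespace"
    filter_tables: bool = False
    collapse: str = "min"
    out_dir: str = "coretf_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError(f"threshold {self.threshold} outside (0, 1]")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "pathway_libraries" in data:
        data["pathway_libraries"] = tuple(data["pathway_libraries"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


@dataclass
class PipelineResult:
    report: CoreTFReport
    tf_table: Optional[EnrichmentTable] = None
    shared: Optional[SharedPathwayResult] = None
    network: Optional[TFNetwork] = None
    hub_ranking: Optional[list[tuple[str, dict]]] = None
    log: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_from_objects(
    selected_genes: Optional[GeneList] = None,
    catalog: Optional[TFCatalog] = None,
    tf_library: Optional[GeneSetLibrary] = None,
    pathway_libraries: Sequence[GeneSetLibrary] = (),
    interactions: Optional[InteractionTable] = None,
    threshold: float = 0.01,
    collapse: str = "min",
    list1: Optional[Sequence[str]] = None,
    list2: Optional[Sequence[str]] = None,
    parameters: Optional[Mapping[str, object]] = None,
) -> PipelineResult:
    """Run the inference stages on in-memory artifacts.

    Stages degrade gracefully: list 1 needs (selected_genes, catalog) or an
    explicit ``list1``; list 2 needs (selected_genes, tf_library) or an
    explicit ``list2``; shared-pathway profiling needs the tf_library plus
    pathway libraries; the network stage needs a non-empty core (falling
    back to list 1 ∪ list 2 nodes is deliberately *not* done — the network
    question is about the core candidates).
    """
    log: dict = {"threshold": threshold, "stages": {}}
    evidence = None

    if list1 is None:
        if selected_genes is None or catalog is None:
            raise ValueError("need selected_genes + catalog, or an explicit list1")
        list1 = select_tfs(selected_genes, catalog)
    log["stages"]["list1"] = {"n_tfs": len(list1)}

    if list2 is None:
        if selected_genes is None or tf_library is None:
            raise ValueError("need selected_genes + tf_library, or an explicit list2")
        list2, evidence = tf_target_enrichment(
            selected_genes, tf_library, threshold=threshold, collapse=collapse
        )
        log["stages"]["list2"] = {
            "n_tfs": len(list2),
            "n_sets_tested": len(tf_library),
            "n_tfs_tested": len(tf_library.sets_by_tf()),
        }
    else:
        log["stages"]["list2"] = {"n_tfs": len(list2), "precomputed": True}

    params = dict(parameters or {})
    params.setdefault("threshold", threshold)
    params.setdefault("collapse", collapse)
    report = call_core_tfs(list1, list2, evidence=evidence, parameters=params)
    log["stages"]["core"] = {"n_core": len(report.core)}

    tf_table = None
    if evidence is not None:
        records = tuple(
            ev.target_enrichment for ev in evidence.values() if ev.target_enrichment
        )
        tf_table = EnrichmentTable(
            records=records, threshold=threshold,
            query_label=selected_genes.label if selected_genes else "query",
        )

    shared = None
    if tf_library is not None and pathway_libraries and len(report.core) >= 2:
        target_sets = {}
        by_tf = tf_library.sets_by_tf()
        for tf in report.core:
            members = sorted(set().union(*(s.members for s in by_tf.get(tf, []))) if by_tf.get(tf) else set())
            target_sets[tf] = GeneList(label=f"{tf}_targets", symbols=tuple(members))
        usable = sum(1 for gl in target_sets.values() if len(gl) > 0)
        if usable >= 2:
            shared = shared_enrichments(target_sets, pathway_libraries, threshold=threshold)
            log["stages"]["shared"] = {
                "n_shared": len(shared.shared),
                "excluded_tfs": list(shared.excluded_tfs),
            }

    network = None
    hub_ranking = None
    if report.core and tf_library is not None:
        network = build_regulatory_network(report.core, tf_library)
        if interactions is not None:
            network = add_ppi_overlay(
                network, interactions,
                {"list1": report.list1, "list2": report.list2},
            )
        hub_ranking = rank_hubs(network)
        log["stages"]["network"] = {
            "n_regulatory_edges": len(network.regulatory_edges),
            "n_ppi_edges": len(network.ppi_edges),
            "top_hub": hub_ranking[0][0] if hub_ranking else None,
        }

    return PipelineResult(
        report=report, tf_table=tf_table, shared=shared,
        network=network, hub_ranking=hub_ranking, log=log,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs per the config, run every stage, persist all outputs.

    Writes, under ``config.out_dir``: the core-TF report (JSON + TSV), the
    collapsed TF enrichment table, shared-pathway tables, network exports
    (edge list, node stats, GraphML) and ``run_log.json`` with parameters,
    input checksums and per-stage record counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    checksums = {}
    universe = None
    if config.background_universe:
        universe = cio.read_gene_list(config.background_universe, label="universe").symbols
        checksums["background_universe"] = _sha256(config.background_universe)

    selected = None
    if config.selected_genes:
        selected = cio.read_gene_list(config.selected_genes, label="selected_genes")
        checksums["selected_genes"] = _sha256(config.selected_genes)
    catalog = None
    if config.tf_catalog:
        catalog = cio.read_tf_catalog(config.tf_catalog, config.tf_catalog_aliases)
        checksums["tf_catalog"] = _sha256(config.tf_catalog)
    tf_library = None
    if config.tf_targets:
        tf_library = cio.read_gmt(
            config.tf_targets,
            background_size=config.background_size,
            parse_tf_names=config.parse_tf_names,
            tf_name_dialect=config.tf_name_dialect,
            background_universe=universe,
        )
        checksums["tf_targets"] = _sha256(config.tf_targets)
    pathway_libs = []
    for p in config.pathway_libraries:
        pathway_libs.append(
            cio.read_gmt(p, background_size=config.background_size, background_universe=universe)
        )
        checksums[f"pathway:{Path(p).stem}"] = _sha256(p)
    interactions = None
    if config.interactions:
        interactions = cio.read_interactions(config.interactions)
        checksums["interactions"] = _sha256(config.interactions)

    list1 = list(cio.read_gene_list(config.list1, label="list1")) if config.list1 else None
    list2 = list(cio.read_gene_list(config.list2, label="list2")) if config.list2 else None

    result = run_from_objects(
        selected_genes=selected,
        catalog=catalog,
        tf_library=tf_library,
        pathway_libraries=pathway_libs,
        interactions=interactions,
        threshold=config.threshold,
        collapse=config.collapse,
        list1=list1,
        list2=list2,
        parameters={
            "background_size": config.background_size,
            "libraries": sorted(checksums),
        },
    )

    cio.write_report(result.report, out / "core_tf_report.json", out / "core_tf_evidence.tsv")
    cio.write_gene_list(list(result.report.list1), out / "list1_selected_tfs.txt")
    cio.write_gene_list(list(result.report.list2), out / "list2_target_enriched_tfs.txt")
    cio.write_gene_list(list(result.report.core), out / "core_tfs.txt")
    if result.tf_table is not None:
        table = result.tf_table
        if config.filter_tables:
            table = EnrichmentTable(
                records=table.significant(), threshold=table.threshold,
                query_label=table.query_label, presorted=True,
            )
        cio.write_enrichment_table(table, out / "tf_target_enrichment.tsv")
    if result.shared is not None:
        (out / "shared_pathways.json").write_text(
            json.dumps(
                {
                    "shared": list(result.shared.shared),
                    "tfs_considered": list(result.shared.tfs_considered),
                    "excluded_tfs": list(result.shared.excluded_tfs),
                    "per_tf_enriched": {
                        tf: sorted(map(list, pairs))
                        for tf, pairs in result.shared.per_tf_enriched.items()
                    },
                },
                indent=2, sort_keys=True,
            ) + "\n"
        )
    if result.network is not None:
        write_edge_list(result.network, out / "network_edges.tsv")
        write_node_stats(result.network, out / "network_node_stats.tsv")
        write_graphml(result.network, out / "network.graphml")

    result.log["parameters"] = dataclasses.asdict(config)
    result.log["input_checksums"] = checksums
    log_payload = dict(result.log)
    import time

    log_payload["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_log.json").write_text(json.dumps(log_payload, indent=2, sort_keys=True) + "\n")
    return result
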