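"""End-to-end orchestration of the screening pipeline.

Stage order: ingredient screen → target mapping → seed-network expansion
(drug side and disease side) → network intersection → degree filter →
core filter → hub selection → enrichment → docking rank.  Every
intermediate artifact is written to the output directory and the run is
summarized in a machine-readable JSON report.  With the same config and
seed the report is byte-identical across runs.

Inputs may come from files (TSV/SIF/GMT) or from the seeded synthetic
generators; each file path, when given, overrides the corresponding
synthetic input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .disease import differential_targets, intersect_cohorts, read_expression
from .docking import DockingSummary, rank_pairs, read_docking_table
from .enrichment import enrich, read_gmt
from .ingredients import read_compound_table, screen_ingredients, write_compound_table
from .network import (
    build_bipartite,
    expand_seed_network,
    intersect_networks,
    read_edge_list,
    read_sif,
    write_sif,
)
from .synthetic import (
    SimulationConfig,
    generate_compound_table,
    generate_docking_matrix,
    generate_expression,
    generate_gene_sets,
    generate_interactome,
    generate_target_map,
)
from .topology import screen

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs: input sources plus stage parameters.

    File paths, when set, override the synthetic generator for that
    input.  ``expression_files`` is a list of (matrix, labels) path
    pairs, one per cohort; ``target_map_file`` a two-column TSV
    (compound, target).
    """

    seed: int = 0
    synthetic: SimulationConfig = field(default_factory=SimulationConfig)
    # optional file inputs
    compound_table_file: str | None = None
    target_map_file: str | None = None
    interactome_file: str | None = None  # .sif or 2-column TSV
    expression_files: list[tuple[str, str]] = field(default_factory=list)
    gene_sets_file: str | None = None
    docking_file: str | None = None
    # stage parameters
    ob_min: float = 30.0
    dl_min: float = 0.18
    alpha: float = 0.05
    lfc_min: float = 1.0
    require_concordant_sign: bool = False
    expansion_depth: int = 1
    degree_factor: float = 2.0
    stage1_cmp: str = "ge"
    stage2_cmp: str = "gt"
    top_k: int = 10
    p_max: float = 0.05
    adjust: bool = True
    n_dock_ligands: int = 7

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SimulationConfig(**self.synthetic)
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "expression_files" in raw:
            raw["expression_files"] = [tuple(p) for p in raw["expression_files"]]
        if "term_size_range" in raw.get("synthetic", {}):
            raw["synthetic"]["term_size_range"] = tuple(raw["synthetic"]["term_size_range"])
        return cls(**raw)


@dataclass
class PipelineReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    config: dict
    counts: dict[str, int]
    candidates: list[str]
    drug_targets: list[str]
    disease_targets: list[str]
    core_targets: list[str]
    hubs: list[str]
    medians: dict[str, float]
    enrichment_significant: list[str]
    docking_best_pair: list | None
    docking_total: float | None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_target_map(path: str | Path) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()  # compound <tab> target
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def _load_interactome(path: str) -> nx.Graph:
    return read_sif(path) if path.endswith(".sif") else read_edge_list(path)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineReport:
    """Execute every stage in order, writing intermediates to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.synthetic

    # --- stage: ingredient screen -----------------------------------------
    if config.compound_table_file:
        table = read_compound_table(config.compound_table_file)
    else:
        table = generate_compound_table(sim)
    candidates = screen_ingredients(table, ob_min=config.ob_min, dl_min=config.dl_min)
    write_compound_table(candidates.records, out / "candidates.tsv")
    logger.info("ingredient screen: %d/%d records retained", len(candidates), len(table))

    # --- stage: interactome + planted truth --------------------------------
    if config.interactome_file:
        interactome = _load_interactome(config.interactome_file)
        planted_module: list[str] = []
    else:
        interactome = generate_interactome(sim)
        planted_module = interactome.graph.get("planted_module", [])
    write_sif(interactome, out / "interactome.sif")

    # --- stage: target mapping --------------------------------------------
    if config.target_map_file:
        target_map = _load_target_map(config.target_map_file)
    else:
        target_map = generate_target_map(
            sim, candidates, sorted(interactome.nodes), ensure=planted_module
        )
    bipartite = build_bipartite(candidates, target_map)
    with open(out / "bipartite.tsv", "w") as fh:
        fh.write("compound\ttarget\n")
        for c, t in sorted(bipartite.links):
            fh.write(f"{c}\t{t}\n")
    drug_targets = bipartite.targets
    logger.info("target mapping: %d putative drug targets", len(drug_targets))

    # --- stage: disease targets -------------------------------------------
    if config.expression_files:
        cohorts = [
            read_expression(m, l, name=f"cohort{i + 1}")
            for i, (m, l) in enumerate(config.expression_files)
        ]
        planted_de: list[str] = []
    else:
        planted = planted_module if planted_module else None
        cohorts, planted_de = generate_expression(sim, planted=planted)
    tables = []
    for ds in cohorts:
        _, t = differential_targets(ds, alpha=config.alpha, lfc_min=config.lfc_min)
        t.to_csv(out / f"de_{ds.name}.tsv", sep="\t", index=False)
        tables.append(t)
    disease_targets = intersect_cohorts(
        tables, require_concordant_sign=config.require_concordant_sign
    )
    (out / "disease_targets.tsv").write_text("".join(f"{g}\n" for g in sorted(disease_targets)))
    logger.info("disease targets: %d genes common to %d cohorts", len(disease_targets), len(tables))

    # --- stage: expansion + intersection -----------------------------------
    drug_net = expand_seed_network(drug_targets, interactome, depth=config.expansion_depth)
    disease_net = expand_seed_network(disease_targets, interactome, depth=config.expansion_depth)
    merged = intersect_networks(drug_net, disease_net)
    write_sif(drug_net, out / "drug_network.sif")
    write_sif(disease_net, out / "disease_network.sif")
    write_sif(merged, out / "merged_network.sif")
    logger.info(
        "networks: drug %d/%d, disease %d/%d, merged %d/%d (nodes/edges)",
        drug_net.number_of_nodes(), drug_net.number_of_edges(),
        disease_net.number_of_nodes(), disease_net.number_of_edges(),
        merged.number_of_nodes(), merged.number_of_edges(),
    )

    # --- stage: topology screen --------------------------------------------
    if merged.number_of_nodes() == 0:
        raise RuntimeError("stage topology_screen: merged network is empty")
    report = screen(
        merged,
        degree_factor=config.degree_factor,
        top_k=config.top_k,
        stage1_cmp=config.stage1_cmp,
        stage2_cmp=config.stage2_cmp,
    )
    write_sif(report.stage1, out / "significant_network.sif")
    (out / "core_targets.tsv").write_text("".join(f"{g}\n" for g in sorted(report.stage2)))
    (out / "hub_targets.tsv").write_text("".join(f"{g}\n" for g in sorted(report.hubs)))
    logger.info(
        "topology screen: %d significant, %d core, %d hub targets",
        report.stage1.number_of_nodes(), len(report.stage2), len(report.hubs),
    )

    # --- stage: enrichment ---------------------------------------------------
    if config.gene_sets_file:
        collection = read_gmt(config.gene_sets_file)
    else:
        collection = generate_gene_sets(sim, sorted(interactome.nodes))
    if len(collection):
        enr = enrich(report.stage2, collection, p_max=config.p_max, adjust=config.adjust)
    else:
        enr = None
    significant_terms: list[str] = []
    if enr is not None:
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        significant_terms = sorted(enr.loc[enr["significant"], "term_id"])

    # --- stage: docking rank -------------------------------------------------
    summary: DockingSummary | None = None
    if config.docking_file:
        summary = rank_pairs(read_docking_table(config.docking_file))
    elif report.hubs:
        ligands = candidates.compounds[: config.n_dock_ligands]
        if ligands:
            matrix = generate_docking_matrix(sim, ligands, sorted(report.hubs))
            summary = rank_pairs(matrix)
    if summary is not None:
        with open(out / "docking_ranking.tsv", "w") as fh:
            fh.write("ligand\treceptor\tenergy\n")
            for lig, rec, e in summary.ranking:
                fh.write(f"{lig}\t{rec}\t{e}\n")

    cfg_echo = dataclasses.asdict(config)
    cfg_echo["synthetic"] = dataclasses.asdict(sim)
    cfg_echo["expression_files"] = [list(p) for p in config.expression_files]
    pipeline_report = PipelineReport(
        version=__version__,
        config=cfg_echo,
        counts={
            "compound_records": len(table),
            "candidates": len(candidates),
            "drug_targets": len(drug_targets),
            "disease_targets": len(disease_targets),
            "interactome_nodes": interactome.number_of_nodes(),
            "interactome_edges": interactome.number_of_edges(),
            "drug_network_nodes": drug_net.number_of_nodes(),
            "drug_network_edges": drug_net.number_of_edges(),
            "disease_network_nodes": disease_net.number_of_nodes(),
            "disease_network_edges": disease_net.number_of_edges(),
            "merged_nodes": merged.number_of_nodes(),
            "merged_edges": merged.number_of_edges(),
            "significant_nodes": report.stage1.number_of_nodes(),
            "significant_edges": report.stage1.number_of_edges(),
            "core_targets": len(report.stage2),
            "hub_targets": len(report.hubs),
            "significant_terms": len(significant_terms),
        },
        candidates=sorted(candidates.compounds),
        drug_targets=sorted(drug_targets),
        disease_targets=sorted(disease_targets),
        core_targets=sorted(report.stage2),
        hubs=sorted(report.hubs),
        medians=report.medians,
        enrichment_significant=significant_terms,
        docking_best_pair=list(summary.best_pair) if summary else None,
        docking_total=summary.total if summary else None,
    )
    (out / "report.json").write_text(pipeline_report.to_json())
    return pipeline_report
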