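"""Seeded synthetic inputs for the whole screening pipeline.

Every public database the screen normally consumes — a background
protein interactome, an ADME-annotated compound table, compound→target
maps, tumor/normal expression cohorts, and gene-set annotation — is
replaced by a generator with a single integer seed, so each downstream
stage is testable without downloads and every run is reproducible.

Generated interactomes grow by preferential attachment (Barabási–Albert):
real PPI degree distributions are heavy-tailed, which is exactly the
structure the median-based topology filters exploit.  Optionally a small
clique ("planted module") is wired into the highest-degree nodes to act
as a known high-centrality ground truth.  Expression cohorts share one
planted set of differentially expressed genes, mirroring several GEO
series profiling the same tumor/normal contrast.  OB is uniform on
[0, 100] and DL uniform on [0, 1] so the 30 % / 0.18 screening thresholds
are exercised on both sides.

Sub-streams are derived deterministically from ``(seed, call-name)``:
one call never perturbs another's randomness.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .disease import ExpressionDataset
from .enrichment import GeneSet, GeneSetCollection
from .ingredients import CandidateSet, CompoundRecord

__all__ = [
    "SimulationConfig",
    "gene_symbols",
    "generate_interactome",
    "generate_compound_table",
    "generate_expression",
    "generate_gene_sets",
    "generate_target_map",
    "generate_docking_matrix",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Counts are per-call sizes; ``seed`` drives every generator through
    deterministic per-call sub-streams.  ``n_module`` > 0 plants a clique
    of that size wired to the ``module_hub_links`` highest-degree nodes of
    the interactome (a known high-centrality module); 0 disables it.
    """

    seed: int = 0
    # interactome
    n_nodes: int = 500
    edges_per_new_node: int = 3
    n_module: int = 0
    module_hub_links: int = 10
    # compounds
    n_herbs: int = 7
    compounds_per_herb: int = 10
    whitelist_rate: float = 0.2
    targets_per_compound: int = 5
    # expression
    n_genes: int = 2000
    n_tumor: int = 20
    n_normal: int = 20
    n_cohorts: int = 3
    n_de: int = 50
    effect_log2fc: float = 2.0
    noise_sd: float = 1.0
    # gene sets
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)

    def __post_init__(self) -> None:
        for name in (
            "n_nodes", "edges_per_new_node", "n_module", "module_hub_links",
            "n_herbs", "compounds_per_herb", "targets_per_compound",
            "n_genes", "n_tumor", "n_normal", "n_cohorts", "n_de", "n_terms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.whitelist_rate <= 1.0:
            raise ValueError(f"config field whitelist_rate must be in [0, 1], got {self.whitelist_rate}")
        if self.n_de > self.n_genes:
            raise ValueError(f"config field n_de ({self.n_de}) must be <= n_genes ({self.n_genes})")
        if self.term_size_range[0] > self.term_size_range[1]:
            raise ValueError(f"config field term_size_range min exceeds max: {self.term_size_range}")

    def substream(self, call_name: str) -> int:
        """Deterministic sub-seed for one generator call, < 2**31."""
        return (self.seed * 1_000_003 + zlib.crc32(call_name.encode())) % (2**31 - 1)


def gene_symbols(n: int) -> list[str]:
    """Synthetic gene-symbol namespace shared by all generators."""
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_interactome(config: SimulationConfig) -> nx.Graph:
    """Connected scale-free interactome via preferential attachment.

    The graph is simple and connected, with node labels from the shared
    symbol namespace.  When ``config.n_module`` > 0, the last ``n_module``
    symbols form a clique whose members each also link to the
    ``module_hub_links`` highest-degree backbone nodes; the member list is
    stored in ``graph.graph["planted_module"]``.
    """
    if config.n_nodes < 2:
        raise ValueError(f"config field n_nodes must be >= 2, got {config.n_nodes}")
    n_backbone = config.n_nodes - config.n_module
    if config.edges_per_new_node < 1 or config.edges_per_new_node >= n_backbone:
        raise ValueError(
            "config field edges_per_new_node must satisfy "
            f"1 <= m < n_nodes - n_module, got {config.edges_per_new_node}"
        )
    symbols = gene_symbols(config.n_nodes)
    sub = config.substream("interactome")
    backbone = nx.barabasi_albert_graph(n_backbone, config.edges_per_new_node, seed=sub)
    g = nx.relabel_nodes(backbone, {i: symbols[i] for i in range(n_backbone)})
    module = symbols[n_backbone:]
    if module:
        # Staggered hub attachment: each member links to its own window of
        # the top-degree pool, so members bridge distinct hub neighborhoods
        # instead of forming one interchangeable (tied-centrality) block.
        pool_size = min(n_backbone, 2 * config.module_hub_links + config.n_module)
        pool = [
            n for n, _ in sorted(g.degree, key=lambda t: (-t[1], t[0]))[:pool_size]
        ]
        stride = max(1, pool_size // max(len(module), 1))
        for i, u in enumerate(module):
            for v in module[i + 1:]:
                g.add_edge(u, v)
            for j in range(min(config.module_hub_links, pool_size)):
                g.add_edge(u, pool[(i * stride + j) % pool_size])
    g.graph["planted_module"] = list(module)
    return g


def generate_compound_table(config: SimulationConfig) -> list[CompoundRecord]:
    """ADME-annotated compound records spanning the screening thresholds.

    OB ~ U(0, 100), DL ~ U(0, 1); each record is independently
    whitelisted with probability ``whitelist_rate``.  Herb labels cycle
    through ``n_herbs`` synthetic names.
    """
    if config.n_herbs < 1 or config.compounds_per_herb < 1:
        raise ValueError("config fields n_herbs and compounds_per_herb must be >= 1")
    rng = np.random.default_rng(config.substream("compounds"))
    records = []
    for h in range(config.n_herbs):
        herb = f"HERB{h + 1}"
        for c in range(config.compounds_per_herb):
            records.append(
                CompoundRecord(
                    herb=herb,
                    compound=f"{herb}_CPD{c + 1}",
                    ob=float(rng.uniform(0, 100)),
                    dl=float(rng.uniform(0, 1)),
                    whitelisted=bool(rng.random() < config.whitelist_rate),
                )
            )
    return records


def generate_expression(
    config: SimulationConfig, planted: list[str] | None = None
) -> tuple[list[ExpressionDataset], list[str]]:
    """Tumor/normal cohorts sharing one planted DE gene set.

    Every cohort contains the same ``n_de`` planted genes shifted by
    ±``effect_log2fc`` in tumor samples (the sign is fixed per gene and
    shared across cohorts); all other genes are null.  Noise is additive
    Gaussian on the log2 scale with sd ``noise_sd``; per-gene baselines
    are redrawn per cohort, as separate microarray series would be.

    Parameters
    ----------
    planted : optional
        Caller-chosen planted gene list (truth-tracking for pipeline
        scenarios).  Default: sampled from the shared namespace.

    Returns
    -------
    (datasets, planted_genes)
    """
    if config.n_de >= config.n_genes:
        raise ValueError(f"config field n_de ({config.n_de}) must be < n_genes ({config.n_genes})")
    if config.n_tumor < 2 or config.n_normal < 2:
        raise ValueError("config fields n_tumor and n_normal must be >= 2")
    genes = gene_symbols(config.n_genes)
    rng = np.random.default_rng(config.substream("expression"))
    if planted is None:
        planted = sorted(rng.choice(genes, size=config.n_de, replace=False).tolist())
    else:
        planted = list(planted)
        unknown = set(planted) - set(genes)
        if unknown:
            raise ValueError(f"planted genes outside namespace: {sorted(unknown)[:5]}")
        if len(planted) > config.n_de:
            raise ValueError("more planted genes supplied than n_de")
        extra_pool = [g for g in genes if g not in set(planted)]
        extra = rng.choice(extra_pool, size=config.n_de - len(planted), replace=False)
        planted = sorted(planted + extra.tolist())
    gene_index = {g: i for i, g in enumerate(genes)}
    signs = np.where(rng.random(len(planted)) < 0.5, -1.0, 1.0)

    datasets = []
    n_samples = config.n_tumor + config.n_normal
    labels = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    for c in range(config.n_cohorts):
        baseline = rng.normal(8.0, 1.0, size=config.n_genes)
        values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
        for g, s in zip(planted, signs):
            values[gene_index[g], : config.n_tumor] += s * config.effect_log2fc
        datasets.append(
            ExpressionDataset(
                genes=list(genes),
                samples=[f"C{c + 1}S{j + 1}" for j in range(n_samples)],
                values=values,
                labels=list(labels),
                name=f"cohort{c + 1}",
            )
        )
    return datasets, planted


def generate_gene_sets(
    config: SimulationConfig,
    universe: list[str],
    spiked: list[str] | None = None,
) -> GeneSetCollection:
    """Random gene-set collection over ``universe``, optionally with a spiked term.

    Each of the ``n_terms`` terms samples its members without replacement;
    sizes are uniform over ``term_size_range``.  ``spiked`` appends one
    extra term whose members are exactly the given list — a known positive
    for enrichment power tests.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ValueError(
            f"config field term_size_range max ({hi}) exceeds universe size ({len(universe)})"
        )
    rng = np.random.default_rng(config.substream("gene_sets"))
    terms = []
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(universe, size=size, replace=False).tolist())
        terms.append(GeneSet(f"TERM{t + 1:04d}", f"synthetic term {t + 1}", members))
    if spiked is not None:
        unknown = set(spiked) - set(universe)
        if unknown:
            raise ValueError(f"spiked genes outside universe: {sorted(unknown)[:5]}")
        terms.append(GeneSet("SPIKED", "spiked ground-truth term", set(spiked)))
    return GeneSetCollection(terms=terms, universe=set(universe))


def generate_target_map(
    config: SimulationConfig,
    candidates: CandidateSet,
    universe: list[str],
    ensure: list[str] | None = None,
) -> dict[str, set[str]]:
    """Compound→target map over an interactome node namespace.

    Each candidate compound receives ``targets_per_compound`` targets
    sampled from ``universe``.  Genes in ``ensure`` (e.g. a planted
    module the simulated drug is meant to hit) are distributed
    round-robin over the compounds in addition.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    rng = np.random.default_rng(config.substream("target_map"))
    compounds = candidates.compounds
    mapping: dict[str, set[str]] = {c: set() for c in compounds}
    k = min(config.targets_per_compound, len(universe))
    for c in compounds:
        mapping[c] = set(rng.choice(universe, size=k, replace=False).tolist())
    if ensure and compounds:
        for i, g in enumerate(ensure):
            mapping[compounds[i % len(compounds)]].add(g)
    return mapping


def generate_docking_matrix(
    config: SimulationConfig, ligands: list[str], receptors: list[str]
):
    """Synthetic binding-energy matrix, uniform on [−8, −4] kcal/mol."""
    from .docking import DockingEnergyTable

    rng = np.random.default_rng(config.substream("docking"))
    energies = np.round(rng.uniform(-8.0, -4.0, size=(len(ligands), len(receptors))), 2)
    return DockingEnergyTable(
        ligands=list(ligands), receptors=list(receptors), energies=energies.tolist()
    )
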