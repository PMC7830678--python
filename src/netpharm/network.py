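"""Protein-interaction network operations.

Interactomes are undirected simple :class:`networkx.Graph` objects whose
nodes are upper-cased gene/protein symbols.  The module builds the
compound-target bipartite network, expands target seed lists against a
background interactome (seeds plus first neighbors, induced edges), and
intersects drug-side and disease-side networks with Cytoscape
merge-intersection semantics (an edge survives only if present in both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .ingredients import CandidateSet

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "normalize_symbol",
    "validate_interactome",
    "build_bipartite",
    "expand_seed_network",
    "intersect_networks",
    "read_sif",
    "write_sif",
    "read_edge_list",
    "write_edge_list",
]


def normalize_symbol(symbol: str) -> str:
    """Node identity is case-normalized symbol string equality."""
    return str(symbol).strip().upper()


def validate_interactome(graph: nx.Graph) -> None:
    """Require an undirected simple graph without self-loops."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("interactome must be an undirected simple graph")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ValueError(f"interactome contains self-loops: {loops[:5]}")


@dataclass
class BipartiteNetwork:
    """Compound-target bipartite network.

    ``links`` are (compound, target) pairs; the two node sets are disjoint
    by construction because targets are symbol-normalized gene names and
    compounds keep their original names.
    """

    compound_nodes: set[str] = field(default_factory=set)
    target_nodes: set[str] = field(default_factory=set)
    links: set[tuple[str, str]] = field(default_factory=set)

    def target_degree(self, target: str) -> int:
        """Number of distinct compounds hitting ``target``."""
        return sum(1 for _, t in self.links if t == target)

    @property
    def targets(self) -> set[str]:
        """Union of linked targets — the putative drug-target list."""
        return {t for _, t in self.links}


def build_bipartite(
    candidates: CandidateSet, target_map: Mapping[str, Iterable[str]]
) -> BipartiteNetwork:
    """Link candidate compounds to their putative targets.

    Every candidate becomes a compound node (isolated if unmapped).  Map
    keys absent from the candidate set are dropped with a warning rather
    than failing the build.
    """
    net = BipartiteNetwork()
    known = set(candidates.compounds)
    net.compound_nodes = set(known)
    for compound, targets in target_map.items():
        if compound not in known:
            logger.warning("target map key %r not in candidate set; links dropped", compound)
            continue
        for t in targets:
            sym = normalize_symbol(t)
            net.target_nodes.add(sym)
            net.links.add((compound, sym))
    return net


def expand_seed_network(
    seeds: Iterable[str], interactome: nx.Graph, depth: int = 1
) -> nx.Graph:
    """Induce the subnetwork of seeds plus their interactors up to ``depth``.

    Returns the subgraph of ``interactome`` induced on
    ``seeds ∪ neighbors^(<=depth)(seeds)`` — every interactome edge with
    both endpoints in that set is kept.  Seeds absent from the interactome
    are retained as isolated nodes (and logged), mirroring how PPI tools
    keep unmapped query symbols visible.  ``depth=0`` induces on the seeds
    alone.
    """
    validate_interactome(interactome)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    seed_set = {normalize_symbol(s) for s in seeds}
    if not seed_set:
        raise ValueError("empty seed set")
    present = seed_set & set(interactome.nodes)
    missing = seed_set - present
    if missing:
        logger.info("%d seed(s) absent from interactome kept as isolated nodes", len(missing))
    keep = set(present)
    frontier = set(present)
    for _ in range(depth):
        nxt = set()
        for s in frontier:
            nxt.update(interactome.neighbors(s))
        frontier = nxt - keep
        keep.update(nxt)
    sub = nx.Graph(interactome.subgraph(keep))
    sub.add_nodes_from(missing)
    return sub


def intersect_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Edge-wise network intersection (Cytoscape merge-intersection).

    Nodes are the node-set intersection; edges are kept only when present
    in BOTH networks.  Endpoints of every kept edge survive by
    construction, so the result is always a valid interactome.
    """
    validate_interactome(a)
    validate_interactome(b)
    out = nx.Graph()
    out.add_nodes_from(set(a.nodes) & set(b.nodes))
    for u, v in a.edges:
        if b.has_edge(u, v):
            out.add_edge(u, v)
    return out


# ---------------------------------------------------------------------------
# Interchange formats

def write_sif(graph: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    """Write as SIF: nodeA <tab> interaction <tab> nodeB; isolated nodes on their own line."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((str(u), str(v)))) for u, v in graph.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{n}\n")


def read_sif(path: str | Path) -> nx.Graph:
    """Read a SIF file into an undirected simple graph."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) >= 3:
                source, _, targets = parts[0], parts[1], parts[2:]
                for t in targets:
                    if t != source:
                        g.add_edge(source, t)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a 2-column TSV edge list (isolated nodes are not representable)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((str(u), str(v)))) for u, v in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] != parts[1]:
                g.add_edge(parts[0], parts[1])
    return g
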