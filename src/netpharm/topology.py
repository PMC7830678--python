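"""Two-stage median-centrality screening of an intersected PPI network.

The screen mirrors the CytoNCA-style workflow used in network pharmacology:

1. *Significant targets* — keep nodes whose degree centrality (DC) is at
   least ``factor`` times the median DC of the merged network (default
   factor 2), and take the induced subnetwork.
2. *Core targets* — recompute DC, betweenness (BC) and closeness (CC) on
   that subnetwork and keep nodes strictly above the median of all three.
3. *Hub targets* — rank the core subnetwork by each of DC, BC, CC, take
   the top-k of each ranking (ties at the boundary included) and intersect
   the three top-k sets.

Centralities are computed on the largest connected component: closeness
is undefined across components, and the leftover nodes are logged and
excluded.  BC is Brandes' unnormalized count; since every comparison in
the screen is a median or a rank, normalization cannot change any output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import networkx as nx
import pandas as pd

from .network import validate_interactome

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenReport",
    "compute_centralities",
    "filter_by_degree",
    "filter_core",
    "select_hubs",
    "screen",
]


def compute_centralities(graph: nx.Graph, graph_id: str = "") -> pd.DataFrame:
    """Per-node DC/BC/CC table on the largest connected component.

    Returns a DataFrame with columns ``node, dc, bc, cc`` where
    ``dc(v)`` is the neighbor count, ``bc(v)`` the unnormalized Brandes
    betweenness, and ``cc(v) = (n_c - 1) / sum_u d(v, u)`` over the
    component of size ``n_c``.  Nodes outside the largest component are
    excluded and logged.  ``graph_id`` is stored in ``df.attrs``.
    """
    validate_interactome(graph)
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities on an empty graph")
    components = sorted(nx.connected_components(graph), key=len, reverse=True)
    lcc = graph.subgraph(components[0])
    dropped = graph.number_of_nodes() - lcc.number_of_nodes()
    if dropped:
        logger.info("%d node(s) outside the largest component excluded from centralities", dropped)
    bc = nx.betweenness_centrality(lcc, normalized=False)
    cc = nx.closeness_centrality(lcc)
    rows = [(n, lcc.degree(n), bc[n], cc[n]) for n in lcc.nodes]
    df = pd.DataFrame(rows, columns=["node", "dc", "bc", "cc"])
    df = df.sort_values("node", kind="stable").reset_index(drop=True)
    df.attrs["graph_id"] = graph_id
    return df


def _cmp(value: float, threshold: float, op: str) -> bool:
    if op == "ge":
        return value >= threshold
    if op == "gt":
        return value > threshold
    raise ValueError(f"comparator must be 'ge' or 'gt', got {op!r}")


def filter_by_degree(graph: nx.Graph, factor: float = 2.0, cmp: str = "ge") -> nx.Graph:
    """Stage-1 screen: induced subgraph of nodes with DC >= factor x median DC.

    The median is taken over all nodes of the input graph (the mean of the
    two middle values when the node count is even).  With ``factor=0`` the
    screen is the identity.
    """
    validate_interactome(graph)
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot screen an empty graph")
    degrees = {n: graph.degree(n) for n in graph.nodes}
    med = median(degrees.values())
    threshold = factor * med
    keep = {n for n, d in degrees.items() if _cmp(d, threshold, cmp)}
    return nx.Graph(graph.subgraph(keep))


def filter_core(graph: nx.Graph, cmp: str = "gt") -> set[str]:
    """Stage-2 screen: nodes strictly above the median of DC, BC and CC.

    Centralities and their medians are recomputed on the input graph
    (the stage-1 subnetwork), not inherited from any parent network.  On
    any vertex-transitive graph the result is empty: no node strictly
    exceeds a value shared by all.
    """
    table = compute_centralities(graph)
    out: set[str] | None = None
    for metric in ("dc", "bc", "cc"):
        med = float(table[metric].median())
        passing = {n for n, v in zip(table["node"], table[metric]) if _cmp(v, med, cmp)}
        out = passing if out is None else out & passing
    assert out is not None
    return out


def select_hubs(table: pd.DataFrame, k: int = 10) -> set[str]:
    """Intersect the top-k nodes of the DC, BC and CC rankings.

    Each metric is ranked descending and the top-k taken *including all
    ties at the k-th value*, which makes the selection deterministic and
    independent of input order.  With k >= the table size every node is
    returned.
    """
    if table.empty:
        raise ValueError("centrality table is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    result: set[str] | None = None
    for metric in ("dc", "bc", "cc"):
        ranked = table.sort_values(metric, ascending=False, kind="stable")
        if len(ranked) <= k:
            top = set(ranked["node"])
        else:
            cutoff = ranked[metric].iloc[k - 1]
            top = set(ranked.loc[ranked[metric] >= cutoff, "node"])
        result = top if result is None else result & top
    assert result is not None
    return result


@dataclass
class ScreenReport:
    """Outcome of the full two-stage screen plus hub selection.

    Invariant: ``hubs ⊆ stage2 ⊆ stage1.nodes ⊆ stage0.nodes``.
    """

    stage0: nx.Graph
    stage1: nx.Graph
    stage2: set[str]
    hubs: set[str]
    medians: dict[str, float] = field(default_factory=dict)


def screen(
    graph: nx.Graph,
    degree_factor: float = 2.0,
    top_k: int = 10,
    stage1_cmp: str = "ge",
    stage2_cmp: str = "gt",
) -> ScreenReport:
    """Run the complete median screen on a merged network."""
    validate_interactome(graph)
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot screen an empty graph")
    medians: dict[str, float] = {
        "stage1_dc": float(median(dict(graph.degree).values()))
    }
    stage1 = filter_by_degree(graph, factor=degree_factor, cmp=stage1_cmp)
    if stage1.number_of_nodes() == 0:
        return ScreenReport(graph, stage1, set(), set(), medians)
    table1 = compute_centralities(stage1, graph_id="stage1")
    for m in ("dc", "bc", "cc"):
        medians[f"stage2_{m}"] = float(table1[m].median())
    stage2 = filter_core(stage1, cmp=stage2_cmp)
    core_graph = nx.Graph(stage1.subgraph(stage2))
    if core_graph.number_of_nodes() == 0:
        return ScreenReport(graph, stage1, stage2, set(), medians)
    core_table = compute_centralities(core_graph, graph_id="core")
    hubs = select_hubs(core_table, k=top_k)
    return ScreenReport(graph, stage1, stage2, hubs, medians)
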