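"""Centralities, the two-stage median screen, and hub selection."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_connected_graph
from netpharm.synthetic import SimulationConfig, generate_interactome
from netpharm.topology import (
    compute_centralities,
    filter_by_degree,
    filter_core,
    screen,
    select_hubs,
)
from oracle_utils import oracle_centralities


def table_of(graph):
    df = compute_centralities(graph)
    return {r.node: (r.dc, r.bc, r.cc) for r in df.itertuples(index=False)}


class TestComputeCentralities:
    def test_triangle_symmetry(self):
        t = table_of(nx.complete_graph(3))
        for dc, bc, cc in t.values():
            assert (dc, bc, cc) == (2, 0.0, 1.0)

    def test_three_node_path_analytical(self):
        t = table_of(nx.path_graph(["a", "b", "c"]))
        assert t["b"] == (2, 1.0, 1.0)
        assert t["a"][0] == 1 and t["a"][1] == 0.0
        assert t["a"][2] == pytest.approx(2 / 3)

    def test_leaf_bc_zero_and_full_adjacency_cc_one(self):
        t = table_of(nx.star_graph(4))
        center = t[0]
        assert center[2] == 1.0  # adjacent to all others
        for leaf in (1, 2, 3, 4):
            assert t[leaf][1] == 0.0

    def test_matches_brute_force_oracle_on_random_graphs(self):
        """DC/BC/CC equal explicit all-pairs geodesic enumeration within 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            g = random_connected_graph(rng, n_max=40)
            got = table_of(g)
            want = oracle_centralities(g.nodes, g.edges)
            for node, (dc, bc, cc) in want.items():
                assert got[node][0] == dc
                assert got[node][1] == pytest.approx(bc, abs=1e-9)
                assert got[node][2] == pytest.approx(cc, abs=1e-9)

    def test_computed_on_largest_component_only(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("X", "Y")])
        df = compute_centralities(g)
        assert set(df["node"]) == {"A", "B", "C"}

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_centralities(nx.Graph())


class TestFilterByDegree:
    def test_star_keeps_only_the_center(self):
        """K1,4 degrees {4,1,1,1,1}: median 1, threshold 2, center alone survives."""
        out = filter_by_degree(nx.star_graph(4))
        assert set(out.nodes) == {0} and out.number_of_edges() == 0

    def test_regular_graph_annihilated(self):
        out = filter_by_degree(nx.cycle_graph(4))
        assert out.number_of_nodes() == 0

    def test_factor_zero_is_identity(self):
        g = generate_interactome(SimulationConfig(seed=2, n_nodes=60))
        out = filter_by_degree(g, factor=0)
        assert set(out.nodes) == set(g.nodes)
        assert set(map(frozenset, out.edges)) == set(map(frozenset, g.edges))

    def test_even_node_count_median_is_mean_of_middle_pair(self):
        # degrees 1,1,2,2 -> median 1.5, threshold 3 -> empty
        g = nx.path_graph(4)
        assert filter_by_degree(g).number_of_nodes() == 0

    def test_strict_comparator_flag(self):
        # star K1,2: degrees {2,1,1}, median 1; ge keeps center, gt also keeps center only
        g = nx.star_graph(2)
        assert set(filter_by_degree(g, factor=2, cmp="ge").nodes) == {0}
        assert set(filter_by_degree(g, factor=1, cmp="gt").nodes) == {0}


class TestFilterCore:
    @pytest.mark.parametrize("g", [nx.cycle_graph(6), nx.complete_graph(5)],
                             ids=["cycle", "complete"])
    def test_vertex_transitive_graphs_empty(self, g):
        assert filter_core(g) == set()

    def test_single_node_graph_empty(self):
        g = nx.Graph()
        g.add_node("A")
        assert filter_core(g) == set()

    def test_barbell_matches_brute_force_median_rules(self):
        """Two K4s joined via two bridge nodes: re-derive the screen by hand."""
        g = nx.barbell_graph(4, 2)
        want_table = oracle_centralities(g.nodes, g.edges)
        med = {
            i: float(np.median([v[i] for v in want_table.values()])) for i in range(3)
        }
        want = {
            n for n, v in want_table.items()
            if v[0] > med[0] and v[1] > med[1] and v[2] > med[2]
        }
        assert filter_core(g) == want


class TestSelectHubs:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["node", "dc", "bc", "cc"])

    def test_small_table_saturates(self):
        t = self.make_table([(f"n{i}", i, i, i / 10) for i in range(5)])
        assert select_hubs(t, k=10) == {f"n{i}" for i in range(5)}

    def test_only_node_topping_all_three_metrics_survives(self):
        """15 rows where X is rank 1 everywhere and nobody else is top-10 on all three."""
        rows = [("X", 100, 100.0, 0.99)]
        for i in range(14):
            dc = 50 - i               # dc top-10: X, n0..n8
            bc = float(i)             # bc top-10: X, n5..n13
            cc = 0.01 * (i - 4) if 5 <= i <= 8 else 0.5 + i / 100
            rows.append((f"n{i}", dc, bc, cc))  # cc bottom: n5..n8
        out = select_hubs(self.make_table(rows), k=10)
        assert out == {"X"}

    def test_identical_rankings_give_shared_top_k(self):
        rows = [(f"n{i}", i, float(i), i / 100) for i in range(20)]
        t = self.make_table(rows)
        assert select_hubs(t, k=5) == {f"n{i}" for i in range(15, 20)}

    def test_boundary_ties_included(self):
        rows = [("a", 5, 5.0, 0.5), ("b", 3, 3.0, 0.3), ("c", 3, 3.0, 0.3), ("d", 1, 1.0, 0.1)]
        t = self.make_table(rows)
        # k=2: the tie at rank 2 (b and c) is included on every metric
        assert select_hubs(t, k=2) == {"a", "b", "c"}

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_hubs(pd.DataFrame(columns=["node", "dc", "bc", "cc"]))
        with pytest.raises(ValueError):
            select_hubs(self.make_table([("a", 1, 1.0, 0.1)]), k=0)


class TestScreenProperties:
    def test_nesting_on_random_interactomes(self):
        """hubs ⊆ core ⊆ stage-1 nodes ⊆ merged nodes, across seeds."""
        for seed in range(15):
            g = generate_interactome(SimulationConfig(seed=seed, n_nodes=120))
            rep = screen(g)
            assert rep.hubs <= rep.stage2 <= set(rep.stage1.nodes) <= set(rep.stage0.nodes)

    def test_bc_scale_invariance(self):
        """Scaling BC by any positive constant changes no screen output."""
        g = generate_interactome(SimulationConfig(seed=33, n_nodes=100))
        stage1 = filter_by_degree(g)
        table = compute_centralities(stage1)
        hubs = select_hubs(table, k=10)
        scaled = table.copy()
        scaled["bc"] = scaled["bc"] * 1e6
        assert select_hubs(scaled, k=10) == hubs
        med = float(table["bc"].median())
        core = {n for n, b in zip(table["node"], table["bc"]) if b > med}
        med_s = float(scaled["bc"].median())
        core_s = {n for n, b in zip(scaled["node"], scaled["bc"]) if b > med_s}
        assert core == core_s

    def test_planted_clique_recovered_as_core(self):
        """A clique wired into the hubs dominates all three centralities."""
        hits = 0
        total = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_nodes=200, n_module=8, module_hub_links=10)
            g = generate_interactome(cfg)
            module = set(g.graph["planted_module"])
            rep = screen(g)
            hits += len(module & rep.stage2)
            total += len(module)
        assert hits / total >= 0.8
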