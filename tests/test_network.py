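"""Typed graph construction, centralities vs a brute-force shortest-path
oracle, hub filtering and ortholog subnetworks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tisspec.io_formats import PairTable
from tisspec.network import (
    ORTHOLOG,
    PHYSICAL,
    build_network,
    centrality,
    export_tables,
    filter_hubs,
    ortholog_pair_subnetwork,
    physical_subgraph,
)


def phys(rows):
    return PairTable("physical", pd.DataFrame(rows, columns=["id_a", "id_b"]))


def ortho(rows):
    return PairTable("ortholog", pd.DataFrame(rows, columns=["id_a", "id_b", "score"]))


def toy_graph():
    gene_sets = {"a": {"testis": {"a1", "a2"}}, "b": {"testis": {"b1"}}}
    return build_network(
        gene_sets,
        {"a": phys([("a1", "a2")]), "b": phys([])},
        ortho([("a1", "b1", 13)]),
        ("a", "b"),
    )


class TestBuild:
    def test_small_construction(self):
        g = toy_graph()
        assert g.number_of_nodes() == 3
        types = sorted(d["edge_type"] for _, _, d in g.edges(data=True))
        assert types == [ORTHOLOG, PHYSICAL]

    def test_physical_edge_outside_sets_omitted(self):
        gene_sets = {"a": {"t": {"a1"}}, "b": {"t": set()}}
        g = build_network(gene_sets, {"a": phys([("a1", "aX")]), "b": phys([])},
                          ortho([]), ("a", "b"))
        assert g.number_of_edges() == 0

    def test_duplicate_physical_rows_single_edge(self):
        gene_sets = {"a": {"t": {"a1", "a2"}}, "b": {"t": set()}}
        g = build_network(
            gene_sets,
            {"a": phys([("a1", "a2"), ("a1", "a2"), ("a2", "a1")]), "b": phys([])},
            ortho([]), ("a", "b"),
        )
        assert g.number_of_edges() == 1

    def test_no_within_species_ortholog_edges_randomized(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            genes_a = [f"a{i}" for i in range(rng.integers(3, 10))]
            genes_b = [f"b{i}" for i in range(rng.integers(3, 10))]
            gene_sets = {"a": {"t": set(genes_a)}, "b": {"t": set(genes_b)}}
            links = ortho(
                [(rng.choice(genes_a), rng.choice(genes_b), 13) for _ in range(5)]
            )
            g = build_network(gene_sets, {"a": phys([]), "b": phys([])}, links, ("a", "b"))
            for u, v, d in g.edges(data=True):
                if d["edge_type"] == ORTHOLOG:
                    assert u[0] != v[0]


def oracle_centrality(g):
    """Brute-force: BFS distance matrix plus explicit shortest-path
    enumeration (DFS over the distance structure), per component."""
    nodes = list(g.nodes)
    dist = {
        s: {t: d for t, d in _bfs(g, s).items()} for s in nodes
    }
    between = {n: 0.0 for n in nodes}
    close = {}
    for comp in nx.connected_components(g):
        comp = list(comp)
        m = len(comp)
        for s, t in itertools.combinations(comp, 2):
            paths = _all_shortest_paths(g, dist, s, t)
            for n in comp:
                if n in (s, t):
                    continue
                through = sum(1 for p in paths if n in p)
                between[n] += through / len(paths)
        norm = (m - 1) * (m - 2) / 2 if m > 2 else 1
        for n in comp:
            between[n] /= norm
            total = sum(dist[n][t] for t in comp if t != n)
            close[n] = (m - 1) / total if total else 0.0
    return between, close


def _bfs(g, s):
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(g, dist, s, t):
    out = []

    def walk(u, path):
        if u == t:
            out.append(path)
            return
        for v in g.neighbors(u):
            if dist[s].get(v) == dist[s][u] + 1 and dist[v].get(t, -1) == dist[s][t] - dist[s][v]:
                walk(v, path + [v])

    walk(s, [s])
    return out


class TestCentrality:
    def test_three_node_path_hand_values(self):
        gene_sets = {"a": {"t": {"a", "b", "c"}}, "b": {"t": set()}}
        g = build_network(
            gene_sets, {"a": phys([("a", "b"), ("b", "c")]), "b": phys([])},
            ortho([]), ("a", "b"),
        )
        table = centrality(g)
        b = ("a", "b")
        assert table.loc[[b], "degree"].iloc[0] == 2
        assert table.loc[[b], "betweenness"].iloc[0] == pytest.approx(1.0)
        assert table.loc[[b], "closeness"].iloc[0] == pytest.approx(1.0)
        assert table.loc[[("a", "a")], "closeness"].iloc[0] == pytest.approx(2 / 3)

    def test_triangle_betweenness_zero(self):
        gene_sets = {"a": {"t": {"x", "y", "z"}}, "b": {"t": set()}}
        g = build_network(
            gene_sets,
            {"a": phys([("x", "y"), ("y", "z"), ("z", "x")]), "b": phys([])},
            ortho([]), ("a", "b"),
        )
        assert (centrality(g)["betweenness"] == 0).all()

    def test_isolated_node(self):
        gene_sets = {"a": {"t": {"solo"}}, "b": {"t": set()}}
        g = build_network(gene_sets, {"a": phys([]), "b": phys([])}, ortho([]), ("a", "b"))
        table = centrality(g)
        assert table.iloc[0]["degree"] == 0
        assert table.iloc[0]["closeness"] == 0.0

    def test_matches_brute_force_oracle_random_graphs(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            n = int(rng.integers(10, 50))
            er = nx.gnp_random_graph(n, 0.12, seed=int(rng.integers(1e6)))
            gene_sets = {"a": {"t": {f"n{i}" for i in er.nodes}}, "b": {"t": set()}}
            g = build_network(
                gene_sets,
                {"a": phys([(f"n{u}", f"n{v}") for u, v in er.edges]), "b": phys([])},
                ortho([]), ("a", "b"),
            )
            table = centrality(g)
            between, close = oracle_centrality(physical_subgraph(g))
            for node in between:
                assert table.loc[[node], "betweenness"].iloc[0] == pytest.approx(
                    between[node], abs=1e-9
                )
                assert table.loc[[node], "closeness"].iloc[0] == pytest.approx(
                    close[node], abs=1e-9
                )

    def test_ortholog_edges_do_not_enter_shortest_paths(self):
        g = toy_graph()
        table = centrality(g)
        # b1 touches only an ortholog edge: physical degree 0, closeness 0
        assert table.loc[[("b", "b1")], "degree"].iloc[0] == 0
        assert table.loc[[("b", "b1")], "closeness"].iloc[0] == 0.0


class TestHubFilter:
    def star(self, leaves):
        gene_sets = {"a": {"t": {"hub", *(f"l{i}" for i in range(leaves))}}, "b": {"t": set()}}
        return build_network(
            gene_sets,
            {"a": phys([("hub", f"l{i}") for i in range(leaves)]), "b": phys([])},
            ortho([]), ("a", "b"),
        )

    def test_star_hub_kept_leaves_dropped(self):
        g = self.star(21)
        sub = filter_hubs(g, min_degree=20)
        assert list(sub.nodes) == [("a", "hub")]

    def test_degree_exactly_twenty_dropped(self):
        g = self.star(20)
        assert filter_hubs(g, min_degree=20).number_of_nodes() == 0

    def test_empty_graph(self):
        g = nx.Graph()
        assert filter_hubs(g, min_degree=20).number_of_nodes() == 0

    def test_idempotent_and_subset(self):
        g = self.star(25)
        once = filter_hubs(g, min_degree=20)
        twice = filter_hubs(once, min_degree=20)
        assert set(once.nodes) <= set(g.nodes)
        # re-filtering uses degrees of the filtered graph; result stays a subset
        assert set(twice.nodes) <= set(once.nodes)


class TestOrthologSubnetwork:
    def test_orphans_removed(self):
        gene_sets = {
            "a": {"t": {"a1", "a2", "a3"}},
            "b": {"t": {"b1", "b2"}},
        }
        g = build_network(
            gene_sets, {"a": phys([]), "b": phys([])}, ortho([("a1", "b1", 13)]), ("a", "b")
        )
        sub = ortholog_pair_subnetwork(g)
        assert set(sub.nodes) == {("a", "a1"), ("b", "b1")}

    def test_unknown_tissue_rejected(self):
        with pytest.raises(KeyError):
            ortholog_pair_subnetwork(toy_graph(), "kidney")

    def test_tissue_restriction(self):
        gene_sets = {"a": {"brain": {"a1"}, "testis": {"a2"}}, "b": {"brain": {"b1"}, "testis": {"b2"}}}
        g = build_network(
            gene_sets, {"a": phys([]), "b": phys([])},
            ortho([("a1", "b1", 13), ("a2", "b2", 13)]), ("a", "b"),
        )
        sub = ortholog_pair_subnetwork(g, "brain")
        assert set(sub.nodes) == {("a", "a1"), ("b", "b1")}

    def test_no_pairs_empty(self):
        gene_sets = {"a": {"t": {"a1"}}, "b": {"t": {"b1"}}}
        g = build_network(gene_sets, {"a": phys([]), "b": phys([])}, ortho([]), ("a", "b"))
        assert ortholog_pair_subnetwork(g).number_of_nodes() == 0


def test_export_tables_shapes():
    g = toy_graph()
    table = centrality(g)
    edges, nodes = export_tables(g, table)
    assert set(edges.columns) == {"source", "target", "edge_type"}
    assert len(nodes) == 3
    assert nodes["has_ortholog"].sum() == 2
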