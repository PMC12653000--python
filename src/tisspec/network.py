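"""Cross-species tissue / interaction / ortholog graph.

Nodes are (species, gene) pairs from the highly-enriched gene sets of both
species; edges are typed ``physical`` (within-species protein interactions)
or ``ortholog`` (cross-species links).  Centrality — degree, betweenness,
closeness — is computed on the physical subgraph only; a strict degree > 20
filter isolates hubs.  Graphs are undirected and unweighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from tisspec.io_formats import PairTable

logger = logging.getLogger(__name__)

PHYSICAL = "physical"
ORTHOLOG = "ortholog"


def _node(species: str, gene: str) -> tuple[str, str]:
    return (species, gene)


def build_network(
    gene_sets: dict[str, dict[str, set[str]]],
    physical: dict[str, PairTable],
    orthologs: PairTable,
    species_pair: tuple[str, str] | None = None,
) -> nx.Graph:
    """Assemble the typed cross-species graph.

    Parameters
    ----------
    gene_sets
        ``{species: {tissue: set of genes}}`` — the highly-enriched gene sets.
    physical
        ``{species: PairTable(kind='physical')}``.
    orthologs
        Filtered ortholog links; ``id_a`` belongs to the first species of
        ``species_pair``, ``id_b`` to the second.

    The node set is the union of all tissue gene sets; physical edges are kept
    only when both endpoints are present, ortholog edges only for links with
    both partners present.
    """
    if species_pair is None:
        species_pair = tuple(gene_sets)
    sp_a, sp_b = species_pair
    g = nx.Graph()
    for species, tissues in gene_sets.items():
        for tissue, genes in tissues.items():
            for gene in genes:
                node = _node(species, gene)
                if not g.has_node(node):
                    g.add_node(node, species=species, gene=gene, tissues=set())
                g.nodes[node]["tissues"].add(tissue)

    for species, table in physical.items():
        if table.kind != "physical":
            raise ValueError(f"physical table for {species} has kind {table.kind!r}")
        n_skipped = 0
        for id_a, id_b in table.rows[["id_a", "id_b"]].itertuples(index=False):
            u, v = _node(species, id_a), _node(species, id_b)
            if u == v:
                continue
            if g.has_node(u) and g.has_node(v):
                g.add_edge(u, v, edge_type=PHYSICAL)
            else:
                n_skipped += 1
        if n_skipped:
            logger.info("%s: omitted %d physical edges outside gene sets", species, n_skipped)

    for row in orthologs.rows.itertuples(index=False):
        u, v = _node(sp_a, row.id_a), _node(sp_b, row.id_b)
        if g.has_node(u) and g.has_node(v):
            g.add_edge(u, v, edge_type=ORTHOLOG)
    for node in g.nodes:
        g.nodes[node]["has_ortholog"] = any(
            d.get("edge_type") == ORTHOLOG for _, _, d in g.edges(node, data=True)
        )
    return g


def physical_subgraph(graph: nx.Graph) -> nx.Graph:
    edges = [
        (u, v) for u, v, d in graph.edges(data=True) if d.get("edge_type") == PHYSICAL
    ]
    sub = nx.Graph()
    sub.add_nodes_from(graph.nodes(data=True))
    sub.add_edges_from(edges)
    return sub


def centrality(graph: nx.Graph, closeness_mode: str = "component") -> pd.DataFrame:
    """Degree, betweenness and closeness per node, on physical edges only.

    Betweenness is normalized by (m-1)(m-2)/2 within each connected component
    of size m; closeness of a node is (m-1)/sum(distances) within its
    component, with isolated nodes scored 0.  ``closeness_mode='harmonic'``
    switches to harmonic closeness scaled by 1/(m-1).
    """
    phys = physical_subgraph(graph)
    degree = dict(phys.degree())
    betweenness: dict = {}
    closeness: dict = {}
    for comp in nx.connected_components(phys):
        sub = phys.subgraph(comp)
        m = len(comp)
        betweenness.update(nx.betweenness_centrality(sub, normalized=m > 2))
        if m == 1:
            closeness[next(iter(comp))] = 0.0
        elif closeness_mode == "component":
            closeness.update(nx.closeness_centrality(sub))
        elif closeness_mode == "harmonic":
            h = nx.harmonic_centrality(sub)
            closeness.update({n: v / (m - 1) for n, v in h.items()})
        else:
            raise ValueError(f"unknown closeness_mode {closeness_mode!r}")
    rows = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    )
    rows.index.name = "node"
    return rows


def filter_hubs(
    graph: nx.Graph, table: pd.DataFrame | None = None, min_degree: int = 20
) -> nx.Graph:
    """Induced subgraph of nodes whose physical degree strictly exceeds
    ``min_degree``; ortholog edges between surviving nodes are retained."""
    if table is None:
        table = centrality(graph)
    keep = set(table.index[table["degree"] > min_degree])
    return graph.subgraph(keep).copy()


def ortholog_pair_subnetwork(graph: nx.Graph, tissue: str | None = None) -> nx.Graph:
    """Restrict to nodes participating in at least one ortholog edge.

    With ``tissue`` given, only nodes annotated to that tissue are kept (an
    unknown tissue raises).  Remaining physical and ortholog edges are
    induced.
    """
    if tissue is not None:
        known = set().union(*(d.get("tissues", set()) for _, d in graph.nodes(data=True))) if graph.number_of_nodes() else set()
        if tissue not in known:
            raise KeyError(f"unknown tissue {tissue!r}")
    keep = set()
    for u, v, d in graph.edges(data=True):
        if d.get("edge_type") == ORTHOLOG:
            keep.update((u, v))
    if tissue is not None:
        keep = {n for n in keep if tissue in graph.nodes[n].get("tissues", set())}
    return graph.subgraph(keep).copy()


def export_tables(graph: nx.Graph, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cytoscape-compatible edge and node attribute tables."""
    edges = pd.DataFrame(
        [
            {
                "source": f"{u[0]}:{u[1]}",
                "target": f"{v[0]}:{v[1]}",
                "edge_type": d.get("edge_type", ""),
            }
            for u, v, d in graph.edges(data=True)
        ]
    )
    nodes = pd.DataFrame(
        [
            {
                "node": f"{n[0]}:{n[1]}",
                "species": d.get("species", ""),
                "gene": d.get("gene", ""),
                "tissues": ";".join(sorted(d.get("tissues", set()))),
                "has_ortholog": d.get("has_ortholog", False),
                "degree": table.loc[[n], "degree"].iloc[0] if n in table.index else 0,
                "betweenness": table.loc[[n], "betweenness"].iloc[0] if n in table.index else 0.0,
                "closeness": table.loc[[n], "closeness"].iloc[0] if n in table.index else 0.0,
            }
            for n, d in graph.nodes(data=True)
        ]
    )
    return edges, nodes


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export (tuple node ids flattened, tissue sets serialized)."""
    g = nx.Graph()
    for n, d in graph.nodes(data=True):
        g.add_node(
            f"{n[0]}:{n[1]}",
            species=d.get("species", ""),
            gene=d.get("gene", ""),
            tissues=";".join(sorted(d.get("tissues", set()))),
            has_ortholog=bool(d.get("has_ortholog", False)),
        )
    for u, v, d in graph.edges(data=True):
        g.add_edge(f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}", edge_type=d.get("edge_type", ""))
    nx.write_graphml(g, path)
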