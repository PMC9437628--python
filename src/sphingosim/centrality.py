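"""Graph construction and centrality analysis of a pathway model.

A pathway network can be viewed either as the drawn bipartite graph --
species nodes and interaction nodes, with edges reactant → interaction,
interaction → product, and read arcs (modifiers) in both directions -- or as
its species projection, where each reaction contributes directed edges from
every species it reads (reactants and modifiers) to every species it
produces.  Both variants, directed or undirected, are available behind the
``kind``/``directed`` switches; reported species centralities for the
flagship model use the directed species projection, the mode that reproduces
the published values.

Betweenness is shortest-path betweenness with endpoints excluded, normalized
by (n-1)(n-2) on directed graphs.  Closeness uses the reachable-set
convention: for a node x with reachable set R(x) (over outgoing paths),
``closeness = |R(x)| / sum of distances``, and 0 when nothing is reachable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import networkx as nx
import pandas as pd

from .model import PathwayModel

__all__ = [
    "model_to_graph",
    "betweenness_centrality",
    "closeness_centrality",
    "CentralityReport",
    "centrality_report",
    "rank_species",
    "write_graphml",
    "write_edge_list",
]

GraphKind = Literal["species", "bipartite"]


def model_to_graph(
    model: PathwayModel,
    kind: GraphKind = "species",
    directed: bool = True,
) -> nx.Graph:
    """Build the interaction graph of a model.

    ``kind="bipartite"`` keeps one node per reaction (named ``rxn:<index>``,
    tagged ``kind="interaction"``) alongside the species nodes; read arcs are
    drawn in both directions.  ``kind="species"`` projects each reaction onto
    directed edges (reactants ∪ modifiers) → products.  Node order is
    deterministic: species in model order, then interactions in model order.
    """
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for s in model.species:
        g.add_node(s.id, kind="species", role=s.role)
    if kind == "bipartite":
        for r in model.reactions:
            rnode = f"rxn:{r.index}"
            g.add_node(rnode, kind="interaction", name=r.name)
            for sid in r.reactants:
                g.add_edge(sid, rnode, kind="reactant")
            for sid in r.products:
                g.add_edge(rnode, sid, kind="product")
            for sid in sorted(r.modifiers):
                g.add_edge(sid, rnode, kind="read-arc")
                if directed:
                    g.add_edge(rnode, sid, kind="read-arc")
    elif kind == "species":
        for r in model.reactions:
            sources = list(r.reactants) + sorted(r.modifiers)
            for src in sources:
                for dst in r.products:
                    if src != dst:
                        g.add_edge(src, dst, kind="interaction")
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    return g


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Normalized shortest-path betweenness of every node.

    Brandes accumulation with endpoints excluded; normalization constant is
    (n-1)(n-2) for directed graphs and (n-1)(n-2)/2 for undirected ones.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return nx.betweenness_centrality(graph, normalized=True, endpoints=False)


def closeness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Reachable-set closeness over outgoing shortest paths (unit weights)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    out: dict[str, float] = {}
    for node in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, node)
        dists.pop(node, None)
        if dists:
            out[node] = len(dists) / sum(dists.values())
        else:
            out[node] = 0.0
    return out


@dataclass
class CentralityReport:
    """Per-species centralities and Fig-3 style degree counts."""

    table: pd.DataFrame  # index species id; betweenness, closeness, in/out degree

    def row(self, species_id: str) -> pd.Series:
        return self.table.loc[species_id]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="species")


def centrality_report(
    model: PathwayModel,
    kind: GraphKind = "species",
    directed: bool = True,
) -> CentralityReport:
    """Centralities (on the requested graph mode) for species nodes only.

    Degree counts are the drawn-network convention independent of mode: a
    reaction counts as incoming when the species is a product, outgoing when
    a reactant, and both ways for a read arc.
    """
    graph = model_to_graph(model, kind=kind, directed=directed)
    bet = betweenness_centrality(graph)
    clo = closeness_centrality(graph)
    rows = []
    for s in model.species:
        n_in, n_out = model.degree_counts(s.id)
        rows.append(
            {
                "betweenness": bet[s.id],
                "closeness": clo[s.id],
                "in_degree": n_in,
                "out_degree": n_out,
            }
        )
    table = pd.DataFrame(rows, index=[s.id for s in model.species])
    return CentralityReport(table)


def rank_species(
    report: CentralityReport,
    metric: str = "betweenness",
    top_n: int | None = None,
) -> list[tuple[str, float]]:
    """Species ranked by descending centrality; ties keep model order."""
    if metric not in ("betweenness", "closeness"):
        raise ValueError(f"unknown metric {metric!r}")
    series = report.table[metric]
    order = sorted(
        range(len(series)), key=lambda i: (-series.iloc[i], i)
    )
    ranked = [(series.index[i], float(series.iloc[i])) for i in order]
    if top_n is not None:
        ranked = ranked[: max(0, top_n)]
    return ranked


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """TSV edge list: source, target, edge kind."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tkind\n")
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('kind', '')}\n")
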