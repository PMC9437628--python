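"""Graph construction and centralities against exhaustive oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from sphingosim.centrality import (
    betweenness_centrality,
    centrality_report,
    closeness_centrality,
    model_to_graph,
    rank_species,
    write_edge_list,
    write_graphml,
)
from sphingosim.model import PathwayModel


# ---------------------------------------------------------------------------
# independent oracles: explicit all-pairs shortest-path counting
# ---------------------------------------------------------------------------

def floyd_warshall_distances(nodes, edges):
    inf = float("inf")
    dist = {(u, v): (0 if u == v else inf) for u in nodes for v in nodes}
    for u, v in edges:
        dist[u, v] = 1
    for w in nodes:
        for u in nodes:
            for v in nodes:
                if dist[u, w] + dist[w, v] < dist[u, v]:
                    dist[u, v] = dist[u, w] + dist[w, v]
    return dist


def count_shortest_paths(nodes, edges, dist):
    """sigma[u, v]: number of shortest u->v paths, by DP in distance order."""
    adj = {u: [] for u in nodes}
    for u, v in edges:
        adj[u].append(v)
    sigma = {}
    for s in nodes:
        order = sorted((n for n in nodes if dist[s, n] < float("inf")),
                       key=lambda n: dist[s, n])
        counts = {n: 0 for n in nodes}
        counts[s] = 1
        for u in order:
            for v in adj[u]:
                if dist[s, v] == dist[s, u] + 1:
                    counts[v] += counts[u]
        for v in nodes:
            sigma[s, v] = counts[v]
    return sigma


def brute_betweenness(graph: nx.DiGraph):
    nodes = list(graph.nodes)
    edges = list(graph.edges)
    n = len(nodes)
    dist = floyd_warshall_distances(nodes, edges)
    sigma = count_shortest_paths(nodes, edges, dist)
    out = {}
    for x in nodes:
        total = 0.0
        for s, t in itertools.permutations(nodes, 2):
            if s == x or t == x or sigma[s, t] == 0:
                continue
            if dist[s, x] + dist[x, t] == dist[s, t]:
                total += sigma[s, x] * sigma[x, t] / sigma[s, t]
        out[x] = total / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return out


def brute_closeness(graph: nx.DiGraph):
    nodes = list(graph.nodes)
    dist = floyd_warshall_distances(nodes, list(graph.edges))
    out = {}
    for x in nodes:
        reach = [dist[x, y] for y in nodes if y != x and dist[x, y] < float("inf")]
        out[x] = len(reach) / sum(reach) if reach else 0.0
    return out


def random_digraph(seed, max_nodes=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    p = rng.uniform(0.15, 0.5)
    for u in range(n):
        for v in range(n):
            if u != v and rng.uniform() < p:
                g.add_edge(u, v)
    return g


class TestAgainstOracles:
    @pytest.mark.parametrize("seed", range(100))
    def test_betweenness_matches_path_enumeration(self, seed):
        g = random_digraph(seed)
        got = betweenness_centrality(g)
        expected = brute_betweenness(g)
        for node in g.nodes:
            assert got[node] == pytest.approx(expected[node], abs=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_closeness_matches_floyd_warshall(self, seed):
        g = random_digraph(seed)
        got = closeness_centrality(g)
        expected = brute_closeness(g)
        for node in g.nodes:
            assert got[node] == pytest.approx(expected[node], abs=1e-12)

    def test_directed_path_betweenness(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert betweenness_centrality(g)["b"] == pytest.approx(0.5)

    def test_closeness_single_neighbor(self):
        g = nx.DiGraph([("a", "b")])
        got = closeness_centrality(g)
        assert got["a"] == 1.0
        assert got["b"] == 0.0  # empty reachable set


class TestModelGraphs:
    def test_bipartite_node_counts(self, flagship):
        g = model_to_graph(flagship, kind="bipartite")
        species = [n for n, d in g.nodes(data=True) if d["kind"] == "species"]
        interactions = [n for n, d in g.nodes(data=True) if d["kind"] == "interaction"]
        assert len(species) == 73
        assert len(interactions) == 51
        assert g.number_of_nodes() == 124

    def test_bipartite_edges_connect_species_and_interactions(self, flagship):
        g = model_to_graph(flagship, kind="bipartite")
        for u, v in g.edges:
            kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            assert kinds == {"species", "interaction"}

    def test_empty_model_gives_empty_graph(self):
        g = model_to_graph(PathwayModel([], []), kind="bipartite")
        assert g.number_of_nodes() == 0

    def test_sources_and_sinks_have_zero_betweenness(self, flagship):
        g = model_to_graph(flagship, kind="species")
        bet = betweenness_centrality(g)
        for node in g.nodes:
            if g.in_degree(node) == 0 or g.out_degree(node) == 0:
                assert bet[node] == 0.0


class TestFlagshipCentralities:
    def test_ceramide_is_the_betweenness_maximum(self, flagship):
        report = centrality_report(flagship)
        ranked = rank_species(report, "betweenness", 2)
        assert ranked[0][0] == "ceramide"
        assert ranked[0][1] == pytest.approx(0.078, abs=0.05)
        assert ranked[1][0] == "actSMase"

    def test_top8_betweenness_set(self, flagship):
        report = centrality_report(flagship)
        top8 = {sid for sid, _ in rank_species(report, "betweenness", 8)}
        assert top8 == {
            "ceramide", "actSMase", "GiCoupledReceptor", "actS1PR",
            "Sphingosine", "recruitFADD", "S1P", "TNFR_TRADD",
        }

    def test_cytochrome_c_closeness(self, flagship):
        report = centrality_report(flagship)
        assert report.row("CytochromeC").closeness == pytest.approx(0.75)

    def test_hub_species_reach_closeness_one(self, flagship):
        report = centrality_report(flagship)
        ones = {s for s, v in rank_species(report, "closeness")
                if v == pytest.approx(1.0)}
        assert {"actCASP2", "actCASP8", "cIAP2", "actCASP3and9"} <= ones

    def test_degree_columns_match_model_counts(self, flagship):
        report = centrality_report(flagship)
        row = report.row("ceramide")
        assert (row.in_degree, row.out_degree) == (6, 7)


class TestRanking:
    def test_top_n_larger_than_species_count(self, toy):
        report = centrality_report(toy)
        assert len(rank_species(report, "betweenness", 100)) == 3

    def test_ties_preserve_model_order(self, toy):
        report = centrality_report(toy)
        assert [s for s, _ in rank_species(report, "betweenness")] == ["A", "B", "C"]

    def test_unknown_metric(self, toy):
        with pytest.raises(ValueError):
            rank_species(centrality_report(toy), "pagerank")


class TestExports:
    def test_graphml_and_edge_list(self, toy, tmp_path):
        g = model_to_graph(toy, kind="bipartite")
        write_graphml(g, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == g.number_of_nodes()
        write_edge_list(g, tmp_path / "edges.tsv")
        lines = (tmp_path / "edges.tsv").read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tkind"
        assert len(lines) == g.number_of_edges() + 1
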