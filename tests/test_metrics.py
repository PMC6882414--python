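"""Centralities, clustering, path statistics and the power-law diagnostic."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import (
    bf_betweenness,
    bf_closeness,
    bf_clustering,
    bf_path_stats,
    random_graph,
)
from codenet.metrics import (
    FitNotApplicableError,
    betweenness,
    closeness,
    clustering,
    compute_metrics,
    degree_distribution,
    degree_metrics,
    density,
    path_stats,
    power_law_fit,
    rank_nodes,
)
from codenet.network import CodeNetwork


def weighted_triangle():
    net = CodeNetwork()
    for n in "abc":
        net.add_node(n, "article")
    net.add_edge("a", "b", "crossref", 1)
    net.add_edge("b", "c", "crossref", 2)
    net.add_edge("a", "c", "crossref", 3)
    return net


def test_degree_and_weighted_degree_on_triangle():
    table = degree_metrics(weighted_triangle())
    assert table["degree"].tolist() == [2, 2, 2]
    assert sorted(table["weighted_degree"]) == [3, 4, 5]


def test_isolated_node_metrics():
    net = CodeNetwork()
    net.add_node("solo", "article")
    table = degree_metrics(net)
    assert table.loc["solo", "degree"] == 0
    assert table.loc["solo", "weighted_degree"] == 0
    assert clustering(net)["solo"] == 0.0


@pytest.mark.parametrize(
    "graph, expected",
    [
        (nx.complete_graph(3), {0: 1.0, 1: 1.0, 2: 1.0}),     # triangle
        (nx.star_graph(4), {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}),
        (nx.cycle_graph(4), {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0}),  # no triangles
    ],
)
def test_clustering_hand_cases(graph, expected):
    assert dict(clustering(graph)) == expected


def test_closeness_hand_cases():
    assert set(closeness(nx.complete_graph(3))) == {1.0}
    path = nx.path_graph(["a", "b", "c"])
    c = closeness(path)
    assert c["b"] == 1.0
    assert c["a"] == pytest.approx(2 / 3)


def test_betweenness_hand_cases():
    assert set(betweenness(nx.complete_graph(4))) == {0.0}
    path = nx.path_graph(["a", "b", "c"])
    assert betweenness(path)["b"] == 1.0
    star = nx.star_graph(4)  # center 0 + 4 leaves: C(4,2) mediated pairs
    assert betweenness(star)[0] == 6.0


def test_path_stats_hand_cases():
    assert path_stats(nx.complete_graph(5)) == {
        "mean_path_length": 1.0, "diameter": 1, "n_components": 1,
        "component_sizes": [5], "giant_size": 5}
    stats = path_stats(nx.path_graph(4))
    assert stats["mean_path_length"] == pytest.approx(10 / 6)
    assert stats["diameter"] == 3
    with pytest.raises(ValueError):
        path_stats(nx.Graph())


def test_density_cases():
    assert density(nx.complete_graph(4)) == 1.0
    k4 = nx.complete_graph(4)
    k4.remove_edge(0, 1)
    assert density(k4) == pytest.approx(5 / 6)
    empty = nx.empty_graph(3)
    assert density(empty) == 0.0
    with pytest.raises(ValueError):
        density(nx.empty_graph(1))


@pytest.mark.parametrize("seed", range(30))
def test_centralities_agree_with_brute_force(seed):
    """Closeness/betweenness/clustering/path stats vs the enumeration oracle."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    g = random_graph(n, float(rng.uniform(0.15, 0.7)), seed)
    c, b, cl = closeness(g), betweenness(g), clustering(g)
    oc, ob, ocl = bf_closeness(g), bf_betweenness(g), bf_clustering(g)
    for node in g.nodes:
        assert c[node] == pytest.approx(oc[node], abs=1e-9)
        assert b[node] == pytest.approx(ob[node], abs=1e-9)
        assert cl[node] == pytest.approx(ocl[node], abs=1e-9)
    stats = path_stats(g)
    mean_len, diam = bf_path_stats(g)
    assert stats["mean_path_length"] == pytest.approx(mean_len)
    assert stats["diameter"] == diam
    assert diam >= math.ceil(mean_len)


def test_centralities_invariant_under_relabeling():
    g = random_graph(10, 0.4, seed=99)
    mapping = {n: f"x{n}" for n in g.nodes}
    h = nx.relabel_nodes(g, mapping)
    cg, ch = closeness(g), closeness(h)
    bg, bh = betweenness(g), betweenness(h)
    for n in g.nodes:
        assert cg[n] == pytest.approx(ch[mapping[n]])
        assert bg[n] == pytest.approx(bh[mapping[n]])


def test_edge_removal_monotonicity():
    g = random_graph(10, 0.5, seed=7)
    before = degree_metrics(g)["degree"]
    u, v = next(iter(g.edges))
    h = g.copy()
    h.remove_edge(u, v)
    after = degree_metrics(h)["degree"]
    assert (after <= before).all()
    if nx.is_connected(g) and nx.is_connected(h):
        assert path_stats(h)["diameter"] >= path_stats(g)["diameter"]


def test_power_law_fit_on_preferential_attachment():
    """Known heavy-tail behaviour of a Barabasi-Albert graph (m=2, n=2000)."""
    g = nx.barabasi_albert_graph(2000, 2, seed=42)
    fit = power_law_fit(g)
    assert 2.0 <= fit.alpha <= 3.5
    assert fit.is_heavy_tailed()
    assert fit.r_squared > 0.5


def test_power_law_fit_rejects_regular_graph():
    g = nx.random_regular_graph(3, 20, seed=1)
    assert degree_distribution(g) == {3: 20}
    with pytest.raises(FitNotApplicableError):
        power_law_fit(g)


def test_rank_nodes_ordering_and_filters():
    net = weighted_triangle()
    net.add_node("Gloss:taxon", "glossary_term")
    net.add_edge("a", "Gloss:taxon", "glossary_usage", 10)
    report = compute_metrics(net)
    assert rank_nodes(report, "degree", 0) == []
    top = rank_nodes(report, "weighted_degree", 2)
    assert top[0][0] == "a" and top[0][1] == 14.0
    only_terms = rank_nodes(report, "degree", 5, kind="glossary_term")
    assert [n for n, _ in only_terms] == ["Gloss:taxon"]
    # deterministic lexicographic tie-break on equal degree
    tied = rank_nodes(report, "degree", 3, kind="article")
    assert [n for n, _ in tied] == sorted([n for n, _ in tied], key=lambda s: s)
    with pytest.raises(KeyError):
        rank_nodes(report, "pagerank", 1)


def test_report_exports(tmp_path):
    report = compute_metrics(weighted_triangle(), fit_power_law=True)
    csv_path = tmp_path / "nodes.csv"
    report.to_csv(csv_path)
    assert csv_path.read_text().startswith("node,degree,weighted_degree")
    text = report.to_json(tmp_path / "global.json")
    assert '"n_nodes": 3' in text
    assert "error" in report.global_stats["power_law"]  # 1 distinct degree value
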