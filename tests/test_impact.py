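"""Ego networks, amendment reach and deletion previews."""

import networkx as nx
import numpy as np
import pytest

from conftest import bf_ego_members, random_graph
from codenet.impact import amendment_impact, article_members, deletion_preview, ego
from codenet.network import CodeNetwork, build_network, simple_view
from codenet.synthetic import SyntheticSpec, generate_code


def star_net(n_leaves=5):
    net = CodeNetwork()
    net.add_node("hub", "article")
    for i in range(n_leaves):
        net.add_node(f"leaf{i}", "article")
        net.add_edge("hub", f"leaf{i}", "crossref")
    return net


def test_isolated_seed():
    net = CodeNetwork()
    net.add_node("solo", "article")
    net.add_node("other", "article")
    r = ego(net, ["solo"], 1)
    assert r.members == {"solo"} and r.n_induced_edges == 0


def test_path_center_reaches_whole_graph():
    g = nx.path_graph(["a", "b", "c"])
    r = ego(g, ["b"], 1)
    assert r.members == {"a", "b", "c"}
    assert r.n_induced_edges == 2
    assert r.coverage_nodes == 1.0 and r.coverage_edges == 1.0


def test_k0_returns_seeds_only():
    net = star_net()
    r = ego(net, ["hub", "leaf0"], 0)
    assert r.members == {"hub", "leaf0"}
    assert r.n_induced_edges == 1  # the hub-leaf0 edge is induced


def test_unknown_seed_is_named():
    with pytest.raises(KeyError, match="Art.999"):
        ego(star_net(), ["Art.999"], 1)


@pytest.mark.parametrize("seed", range(15))
def test_ego_members_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    g = random_graph(int(rng.integers(5, 13)), float(rng.uniform(0.15, 0.6)), seed)
    nodes = sorted(g.nodes)
    seeds = [nodes[0]] if rng.random() < 0.5 else nodes[:2]
    for k in range(4):
        assert ego(g, seeds, k).members == bf_ego_members(g, seeds, k)


@pytest.mark.parametrize("seed", range(8))
def test_coverage_monotone_in_k_and_seed_inclusion(seed):
    g = random_graph(12, 0.3, seed)
    nodes = sorted(g.nodes)
    prev = -1.0
    for k in range(4):
        cov = ego(g, [nodes[0]], k).coverage_nodes
        assert cov >= prev
        prev = cov
    small = ego(g, nodes[:1], 2)
    big = ego(g, nodes[:3], 2)
    assert small.members <= big.members


def test_amendment_impact_star_leaf():
    """Seeding one leaf of a star at k=1 covers exactly 2/N of the nodes."""
    net = star_net(5)
    r = ego(net, ["leaf0"], 1)
    assert r.coverage_nodes == pytest.approx(2 / 6)


def test_amendment_impact_all_seeds_full_coverage():
    net = star_net()
    all_ids = [n for n, _ in net.nodes()]
    r = ego(net, all_ids, 2)
    assert r.coverage_nodes == 1.0 and r.coverage_edges == 1.0


def test_amendment_seeds_are_article_with_descendants():
    doc, _ = generate_code(SyntheticSpec(n_articles=10, n_glossary=12, seed=6))
    net = build_network(doc)
    members = article_members(net, [3])
    assert "Art.3" in members
    assert all(m == "Art.3" or m.startswith(("Art.3.", "Rec.3", "Ex.3"))
               for m in members)
    assert article_members(net, [3], whole_article=False) == ["Art.3"]
    report, narrative = amendment_impact(net, [3, 5], 2)
    assert report.members_per_k[1] <= report.members_per_k[2]
    assert "first-degree reach" in narrative and "second-degree reach" in narrative


def test_deletion_preview_isolated_node():
    net = CodeNetwork()
    net.add_node("solo", "article")
    net.add_node("a", "article")
    net.add_node("b", "article")
    net.add_edge("a", "b", "crossref")
    d = deletion_preview(net, "solo")
    assert d.after["n_edges"] == d.before["n_edges"]
    assert d.after["n_nodes"] == d.before["n_nodes"] - 1


def test_deleting_star_center_shatters_graph():
    net = star_net(5)
    d = deletion_preview(net, "hub")
    assert d.after["n_components"] == 5
    assert d.after["n_edges"] == 0


def test_deletion_consistent_with_first_degree_ego():
    """E drops by exactly the node's incident edges, all inside its 1-ego."""
    doc, _ = generate_code(SyntheticSpec(n_articles=10, n_glossary=12, seed=2))
    net = build_network(doc)
    g = simple_view(net)
    node = "Art.5"
    d = deletion_preview(net, node)
    assert d.before["n_edges"] - d.after["n_edges"] == g.degree(node)
    assert g.degree(node) <= d.first_degree.n_induced_edges


def test_deletion_preview_is_pure_and_reversible():
    net = star_net(4)
    before = {(u, v, k, w) for u, v, k, w in net.edges()}
    d = deletion_preview(net, "leaf1")
    assert {(u, v, k, w) for u, v, k, w in net.edges()} == before
    # re-inserting the removed node and edges restores the original graph
    g = simple_view(net)
    g2 = g.copy()
    removed = [(u, v, d_) for u, v, d_ in g.edges(data=True) if "leaf1" in (u, v)]
    g2.remove_node("leaf1")
    g2.add_node("leaf1", **g.nodes["leaf1"])
    g2.add_edges_from(removed)
    assert nx.utils.graphs_equal(g, g2)
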