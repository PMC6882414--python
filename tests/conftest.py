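"""Shared fixtures and brute-force oracles.

The oracle functions here deliberately avoid the library's (and
networkx's) centrality code paths: distances come from a hand-rolled BFS,
shortest paths are enumerated by DFS over the distance field, clustering
from a triple loop. They are only feasible on tiny graphs, which is the
point — they are the independent ground truth the fast implementations
are checked against.
"""

from __future__ import annotations

import math
from collections import deque

import networkx as nx
import pytest

from codenet.document import CodeDocument, GlossaryEntry, Provision, parse_document
from codenet.refs import Kind, ProvisionRef

# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------

def bf_bfs_distances(adj: dict, source) -> dict:
    """Plain BFS hop distances from source (hand-rolled, no networkx)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def as_adj(g: nx.Graph) -> dict:
    return {u: sorted(g.neighbors(u)) for u in g.nodes}


def bf_closeness(g: nx.Graph) -> dict:
    """c_i = r_i / sum(distances to the r_i reachable nodes); 0 for isolates."""
    adj = as_adj(g)
    out = {}
    for u in g.nodes:
        dist = bf_bfs_distances(adj, u)
        total = sum(d for v, d in dist.items() if v != u)
        r = len(dist) - 1
        out[u] = r / total if total else 0.0
    return out


def bf_clustering(g: nx.Graph) -> dict:
    out = {}
    for u in g.nodes:
        nbrs = list(g.neighbors(u))
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        links = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if g.has_edge(nbrs[i], nbrs[j])
        )
        out[u] = 2.0 * links / (k * (k - 1))
    return out


def _all_shortest_paths(adj: dict, dist: dict, source, target) -> list[list]:
    """Enumerate every shortest path by DFS backwards over the BFS field."""
    paths = []

    def walk(node, acc):
        if node == source:
            paths.append([source] + acc)
            return
        for prev in adj[node]:
            if dist.get(prev, math.inf) == dist[node] - 1:
                walk(prev, [node] + acc)

    if target in dist:
        walk(target, [])
    return paths


def bf_betweenness(g: nx.Graph) -> dict:
    """Unnormalised betweenness by full shortest-path enumeration."""
    adj = as_adj(g)
    nodes = sorted(g.nodes)
    out = {u: 0.0 for u in nodes}
    for i, s in enumerate(nodes):
        dist = bf_bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for path in paths:
                for interior in path[1:-1]:
                    out[interior] += 1.0 / len(paths)
    return out


def bf_path_stats(g: nx.Graph) -> tuple[float, int]:
    """(mean shortest-path length, diameter) on the largest component."""
    comps = sorted(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    giant = comps[-1]
    adj = as_adj(g)
    total, pairs, diam = 0, 0, 0
    for u in giant:
        dist = bf_bfs_distances(adj, u)
        for v in giant:
            if v != u:
                total += dist[v]
                pairs += 1
                diam = max(diam, dist[v])
    return (total / pairs if pairs else 0.0, diam)


def bf_ego_members(g: nx.Graph, seeds, k: int) -> set:
    """{v : min hop distance from any seed <= k} by per-seed BFS."""
    adj = as_adj(g)
    members = set()
    for s in seeds:
        for v, d in bf_bfs_distances(adj, s).items():
            if d <= k:
                members.add(v)
    return members


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


# ----------------------------------------------------------------------
# document fixtures
# ----------------------------------------------------------------------

TOY_INDENTED = """\
!edition: toy fixture
Preamble. Of scope
  This code governs toy names and cites Art. 2 once.
Article 1. Availability
  An available name is one that is published, see the Glossary.
  1.1. Publication
    Printed works only; cf. Art. 2.
  1.2. Dates
    The date is that of Art. 1.1 and also Art. 2.
Article 2. Validity
  The valid name is the oldest, per Art. 1 and Art. 1.
  Recommendation 2A. Citation
    Authors should cite Art. 1.1.
  Example.
    The name vakrel tor is valid under Art. 2.
Glossary.
  available name [availability] = a name that satisfies Art. 1
  valid name = the correct available name of a taxon
Appendix A. Ethics
  Be kind to fellow toy taxonomists.
"""


@pytest.fixture
def toy_doc() -> CodeDocument:
    return parse_document(TOY_INDENTED)


@pytest.fixture
def two_article_doc() -> CodeDocument:
    """Articles 1 and 2; Art.1 has sub-articles 1.1 and 1.2 (5 provisions total)."""
    doc = CodeDocument()
    a1 = Provision(ProvisionRef(Kind.ARTICLE, (1,)), "One")
    a1.children = [
        Provision(ProvisionRef(Kind.SUBARTICLE, (1, 1)), body="first part"),
        Provision(ProvisionRef(Kind.SUBARTICLE, (1, 2)), body="second part"),
    ]
    a2 = Provision(ProvisionRef(Kind.ARTICLE, (2,)), "Two",
                   body="cites Art. 1 here and Art. 1 again")
    doc.articles = [a1, a2]
    return doc


@pytest.fixture
def toy_glossary() -> list[GlossaryEntry]:
    return [
        GlossaryEntry("nomen nudum"),
        GlossaryEntry("unavailable name"),
        GlossaryEntry("name"),
    ]
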