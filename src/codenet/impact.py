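"""Ego networks and revision-impact reports.

When a provision of a code is amended or deleted, every node within a few
hops of it may be affected: the first-degree ego network holds the
directly cited and citing provisions plus shared glossary vocabulary, the
second degree everything those touch, and so on. These reports quantify
the reach of a proposed change before it is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .metrics import density as _density
from .network import CodeNetwork, simple_view
from .refs import Kind, ProvisionRef

__all__ = ["EgoReport", "DeletionPreview", "ego", "article_members",
           "amendment_impact", "deletion_preview"]


@dataclass
class EgoReport:
    """The k-hop neighbourhood of a seed set with its induced subgraph.

    ``coverage_nodes`` and ``coverage_edges`` are fractions of the *whole*
    network's node and simple-view edge counts — the denominators include
    glossary nodes.
    """

    seeds: tuple[str, ...]
    k: int
    members: frozenset[str]
    n_induced_edges: int
    coverage_nodes: float
    coverage_edges: float
    members_per_k: dict[int, int] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def summary(self) -> str:
        lines = [
            f"ego network of {len(self.seeds)} seed(s) at degree k={self.k}",
            f"  members: {self.n_members} nodes ({self.coverage_nodes:.2%} of the network)",
            f"  induced edges: {self.n_induced_edges} ({self.coverage_edges:.2%} of all edges)",
        ]
        for kk, n in sorted(self.members_per_k.items()):
            lines.append(f"  within {kk} hop(s): {n} nodes")
        return "\n".join(lines)


def _resolve_seeds(g: nx.Graph, seeds) -> list[str]:
    out = []
    for s in seeds:
        sid = s.canonical if isinstance(s, ProvisionRef) else str(s)
        if sid not in g:
            raise KeyError(f"unknown seed node {sid!r}")
        out.append(sid)
    return out


def ego(net, seeds, k: int) -> EgoReport:
    """BFS ball of radius ``k`` around a seed set on the simple view.

    ``k=0`` returns the seeds themselves; ``k=1`` the "first degree"
    neighbourhood in the field's terminology. Induced edges are edges of the simple view with
    both endpoints inside the ball, counted once.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    g = simple_view(net) if isinstance(net, CodeNetwork) else net
    seed_ids = _resolve_seeds(g, seeds if not isinstance(seeds, (str, ProvisionRef)) else [seeds])
    members: set[str] = set(seed_ids)
    frontier = set(seed_ids)
    per_k = {0: len(members)}
    for kk in range(1, k + 1):
        frontier = {nbr for node in frontier for nbr in g.neighbors(node)} - members
        members |= frontier
        per_k[kk] = len(members)
    sub = g.subgraph(members)
    n, e = g.number_of_nodes(), g.number_of_edges()
    return EgoReport(
        seeds=tuple(seed_ids),
        k=k,
        members=frozenset(members),
        n_induced_edges=sub.number_of_edges(),
        coverage_nodes=len(members) / n if n else 0.0,
        coverage_edges=sub.number_of_edges() / e if e else 0.0,
        members_per_k=per_k,
    )


def article_members(net: CodeNetwork, article_nums: list[int],
                    whole_article: bool = True) -> list[str]:
    """All network nodes belonging to the given articles.

    With ``whole_article`` (default) this is each article node plus all of
    its descendants — sub-articles, recommendations and examples — matching
    how amendments are announced at the article level; otherwise only the
    article nodes themselves. Glossary terms are never included implicitly.
    """
    wanted = set(article_nums)
    out: list[str] = []
    for node_id, data in net.nodes():
        if data.get("kind") == Kind.GLOSSARY_TERM.value:
            continue
        try:
            ref = ProvisionRef.parse(node_id)
        except Exception:
            continue
        if not ref.path or ref.kind is Kind.CHAPTER:
            continue
        if ref.kind is Kind.APPENDIX:
            continue
        if ref.path[0] in wanted and (whole_article or
                                      (ref.kind is Kind.ARTICLE)):
            out.append(node_id)
    return out


def amendment_impact(net: CodeNetwork, article_nums: list[int], k: int,
                     whole_article: bool = True) -> tuple[EgoReport, str]:
    """Reach of an amendment touching the given articles.

    Seeds are every node belonging to the amended articles (article node
    plus descendants by default); the report gives node and edge coverage
    for each degree up to ``k``, plus a human-readable narrative.
    """
    seeds = article_members(net, article_nums, whole_article=whole_article)
    if not seeds:
        raise KeyError(f"no network nodes found for articles {article_nums}")
    report = ego(net, seeds, k)
    g = simple_view(net)
    n = g.number_of_nodes()
    lines = [
        f"amendment of article(s) {', '.join(map(str, article_nums))}: "
        f"{len(seeds)} provision node(s) amended",
    ]
    for kk in range(1, k + 1):
        cov = report.members_per_k[kk] / n
        label = {1: "first", 2: "second", 3: "third"}.get(kk, f"{kk}th")
        lines.append(
            f"  {label}-degree reach: {report.members_per_k[kk]} nodes "
            f"({cov:.1%} of the network)")
    return report, "\n".join(lines)


@dataclass
class DeletionPreview:
    """What deleting one node would do: its neighbourhoods and the global
    descriptor deltas. The input network is never modified."""

    ref: str
    first_degree: EgoReport
    second_degree: EgoReport
    before: dict
    after: dict

    def summary(self) -> str:
        b, a = self.before, self.after
        return "\n".join([
            f"deleting {self.ref}:",
            f"  direct connections: {self.first_degree.n_members - 1} nodes, "
            f"{self.first_degree.n_induced_edges} induced edges",
            f"  second-degree reach: {self.second_degree.n_members - 1} nodes "
            f"({self.second_degree.coverage_nodes:.1%} of the network)",
            f"  nodes: {b['n_nodes']} -> {a['n_nodes']}; "
            f"edges: {b['n_edges']} -> {a['n_edges']}; "
            f"components: {b['n_components']} -> {a['n_components']}",
        ])


def deletion_preview(net: CodeNetwork, ref) -> DeletionPreview:
    """Preview the removal of one provision node (pure function).

    Reports the node's first- and second-degree ego networks on the intact
    network, then the global descriptors (N, E, density, components) after
    removing the node and its incident edges.
    """
    g = simple_view(net)
    rid = ref.canonical if isinstance(ref, ProvisionRef) else str(ref)
    if rid not in g:
        raise KeyError(f"unknown node {rid!r}")
    first = ego(g, [rid], 1)
    second = ego(g, [rid], 2)

    def _globals(graph: nx.Graph) -> dict:
        return {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "density": _density(graph) if graph.number_of_nodes() >= 2 else float("nan"),
            "n_components": nx.number_connected_components(graph)
            if graph.number_of_nodes() else 0,
        }

    after_g = g.copy()
    after_g.remove_node(rid)
    return DeletionPreview(ref=rid, first_degree=first, second_degree=second,
                           before=_globals(g), after=_globals(after_g))
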