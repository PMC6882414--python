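"""The typed, weighted network of a code document.

Nodes are structural units (preamble, articles, sub-articles,
recommendations, examples, appendices, optionally chapters) plus one node
per glossary term. Three edge types connect them:

``structural``
    parent -> child containment (weight 1), forming a forest;
``crossref``
    explicit citation, weight = aggregated mention count;
``glossary_usage``
    provision -> glossary term, weight = occurrence count.

Edges are stored directed (citing -> cited, user -> term) but every
analysis in :mod:`codenet.metrics` runs on the undirected *simple view*,
where the types of each unordered pair are collapsed by summing weights —
the convention of standard network tools, since the source system never
distinguishes in- from out-degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .document import CodeDocument
from .extraction import GlossaryMatcher, extract_references
from .refs import Kind, ProvisionRef

__all__ = [
    "EDGE_TYPES",
    "BuildOptions",
    "CodeNetwork",
    "DanglingReferenceError",
    "build_network",
    "filter_network",
    "simple_view",
]

logger = logging.getLogger(__name__)

EDGE_TYPES = ("structural", "crossref", "glossary_usage")


class DanglingReferenceError(KeyError):
    """A cross-reference points at a node absent from the network."""


@dataclass(frozen=True)
class BuildOptions:
    """Switches controlling which nodes and edges the builder emits.

    The totals of a published network generally cannot be decomposed into
    one fixed convention, so every optional node class and edge type can be
    toggled to reproduce either a containment+reference network (defaults)
    or a references-only one.
    """

    structural: bool = True
    crossref: bool = True
    glossary_usage: bool = True
    include_preamble: bool = True
    include_appendices: bool = True
    include_glossary_section: bool = True
    include_chapters: bool = False
    definition_crossrefs: bool = True  # citations inside glossary definitions
    strict: bool = False               # dangling reference -> error instead of skip+log


class CodeNetwork:
    """Typed multigraph keyed by canonical ref strings.

    At most one edge may exist per (ordered pair, type); re-adding
    accumulates weight. Node identifiers are canonical ref strings
    (``Art.23.1``, ``Gloss:taxon``) — or arbitrary strings for networks
    loaded from external files.
    """

    def __init__(self, directed: bool = True):
        self.directed = directed
        self.g = nx.MultiDiGraph()

    # -- construction ---------------------------------------------------
    def add_node(self, node_id: str, kind: str, label: str = "", word_count: int = 0) -> None:
        self.g.add_node(node_id, kind=str(kind), label=label or node_id,
                        word_count=int(word_count))

    def add_edge(self, source: str, target: str, type: str, weight: int = 1) -> None:
        if source == target:
            raise ValueError(f"self-loop on {source}")
        for endpoint in (source, target):
            if endpoint not in self.g:
                raise DanglingReferenceError(endpoint)
        # one edge per (unordered pair, type): a reverse citation accumulates
        # onto the existing edge, keeping the first-seen direction
        if self.g.has_edge(source, target, key=type):
            self.g[source][target][type]["weight"] += int(weight)
        elif self.g.has_edge(target, source, key=type):
            self.g[target][source][type]["weight"] += int(weight)
        else:
            self.g.add_edge(source, target, key=type, type=type, weight=int(weight))

    # -- inspection -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self) -> Iterable[tuple[str, dict]]:
        return self.g.nodes(data=True)

    def edges(self) -> Iterable[tuple[str, str, str, int]]:
        """(source, target, type, weight) tuples in insertion order."""
        for u, v, k, d in self.g.edges(keys=True, data=True):
            yield u, v, k, d["weight"]

    def kind_of(self, node_id: str) -> str:
        return self.g.nodes[node_id].get("kind", "unknown")

    def node_census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, data in self.g.nodes(data=True):
            out[data.get("kind", "unknown")] = out.get(data.get("kind", "unknown"), 0) + 1
        return out

    def edge_census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, k in self.g.edges(keys=True):
            out[k] = out.get(k, 0) + 1
        return out

    def copy(self) -> "CodeNetwork":
        dup = CodeNetwork(self.directed)
        dup.g = self.g.copy()
        return dup

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodeNetwork):
            return NotImplemented
        return (
            dict(self.g.nodes(data=True)) == dict(other.g.nodes(data=True))
            and {(u, v, k): d["weight"] for u, v, k, d in self.g.edges(keys=True, data=True)}
            == {(u, v, k): d["weight"] for u, v, k, d in other.g.edges(keys=True, data=True)}
        )

    # -- invariants -----------------------------------------------------
    def check_invariants(self) -> list[str]:
        """Return human-readable descriptions of violated network invariants."""
        problems: list[str] = []
        for u, v, k, d in self.g.edges(keys=True, data=True):
            if u == v:
                problems.append(f"self-loop on {u}")
            if k not in EDGE_TYPES:
                problems.append(f"unknown edge type {k!r} on {u}->{v}")
            if d["weight"] < 1:
                problems.append(f"non-positive weight on {u}->{v} ({k})")
            gloss_ends = sum(self.kind_of(n) == Kind.GLOSSARY_TERM.value for n in (u, v))
            if k == "glossary_usage" and gloss_ends != 1:
                problems.append(f"glossary_usage edge {u}->{v} has {gloss_ends} glossary endpoints")
            if k == "structural" and gloss_ends:
                problems.append(f"structural edge {u}->{v} touches a glossary term")
        structural = nx.Graph(
            (u, v) for u, v, k in self.g.edges(keys=True) if k == "structural")
        if structural.number_of_edges() and not nx.is_forest(structural):
            problems.append("structural edges contain a cycle")
        seen_pairs: set[tuple[frozenset, str]] = set()
        for u, v, k in self.g.edges(keys=True):
            key = (frozenset((u, v)), k)
            if key in seen_pairs:
                problems.append(f"duplicate {k} edge between {u} and {v}")
            seen_pairs.add(key)
        return problems


# ----------------------------------------------------------------------
# building from a document
# ----------------------------------------------------------------------

def build_network(doc: CodeDocument, options: BuildOptions | None = None) -> CodeNetwork:
    """Assemble the typed weighted network of a code document.

    Deterministic for fixed input and options: nodes are inserted in
    document order, edges in extraction order. Self-references and
    references to a provision's own ancestors are dropped (the structural
    chain already links them); a reference to a missing target raises
    :class:`DanglingReferenceError` under ``options.strict``, otherwise it
    is skipped and logged.
    """
    opts = options or BuildOptions()
    net = CodeNetwork(directed=True)

    provisions = []
    for prov in doc.provisions():
        if prov.ref.kind is Kind.PREAMBLE and not opts.include_preamble:
            continue
        if prov.ref.kind is Kind.APPENDIX and not opts.include_appendices:
            continue
        provisions.append(prov)
        label = prov.ref.canonical if not prov.title else f"{prov.ref.canonical} {prov.title}"
        net.add_node(prov.ref.canonical, prov.ref.kind.value, label,
                     len(prov.body.split()))
    if opts.include_chapters:
        for ch in doc.chapters:
            net.add_node(ch.ref.canonical, Kind.CHAPTER.value,
                         f"{ch.ref.canonical} {ch.title}".strip(), 0)
    if doc.glossary and opts.include_glossary_section:
        net.add_node("Glossary", Kind.GLOSSARY_SECTION.value, "Glossary", 0)
    for entry in doc.glossary:
        net.add_node(entry.ref.canonical, Kind.GLOSSARY_TERM.value, entry.term,
                     len(entry.definition.split()))

    if opts.structural:
        for prov in provisions:
            parent = prov.ref.parent
            if parent is not None and parent.canonical in net.g:
                net.add_edge(parent.canonical, prov.ref.canonical, "structural")
        if opts.include_chapters:
            for ch in doc.chapters:
                for art in doc.articles:
                    if ch.first_article <= art.ref.path[0] <= ch.last_article:
                        net.add_edge(ch.ref.canonical, art.ref.canonical, "structural")

    def _add_crossrefs(source_ref: ProvisionRef, body: str) -> None:
        for hit in extract_references(body):
            target = hit.target
            if target == source_ref or target.is_ancestor_of(source_ref):
                continue  # containment chain already links these
            if target.canonical not in net.g:
                if opts.strict:
                    raise DanglingReferenceError(
                        f"{source_ref.canonical} cites missing {target.canonical}")
                logger.debug("skipping dangling reference %s -> %s",
                             source_ref.canonical, target.canonical)
                continue
            net.add_edge(source_ref.canonical, target.canonical, "crossref", hit.count)

    if opts.crossref:
        for prov in provisions:
            _add_crossrefs(prov.ref, prov.body)
        if opts.definition_crossrefs:
            for entry in doc.glossary:
                _add_crossrefs(entry.ref, entry.definition)

    if opts.glossary_usage and doc.glossary:
        matcher = GlossaryMatcher(doc.glossary)
        for prov in provisions:
            for hit in matcher.hits(prov.body):
                target = f"Gloss:{hit.term}"
                if target != prov.ref.canonical:
                    net.add_edge(prov.ref.canonical, target, "glossary_usage", hit.count)
    return net


# ----------------------------------------------------------------------
# views
# ----------------------------------------------------------------------

def filter_network(net: CodeNetwork,
                   drop_kinds: Iterable[str] = (),
                   drop_edge_types: Iterable[str] = ()) -> CodeNetwork:
    """Induced subnetwork after removing node kinds and edge types.

    Removing a node kind removes all its incident edges; invariants are
    preserved by construction. Dropping nothing returns an equal copy.
    """
    kinds = {str(k) for k in drop_kinds}
    types = {str(t) for t in drop_edge_types}
    out = CodeNetwork(net.directed)
    for node_id, data in net.nodes():
        if data.get("kind") not in kinds:
            out.add_node(node_id, data.get("kind", "unknown"),
                         data.get("label", node_id), data.get("word_count", 0))
    for u, v, k, w in net.edges():
        if k in types or u not in out.g or v not in out.g:
            continue
        out.add_edge(u, v, k, w)
    return out


def simple_view(net: CodeNetwork) -> nx.Graph:
    """Undirected weighted simple graph: per unordered pair, weights of all
    edge types and both directions are summed. All metrics run on this view."""
    g = nx.Graph()
    for node_id, data in net.nodes():
        g.add_node(node_id, **data)
    for u, v, _, w in net.edges():
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g
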