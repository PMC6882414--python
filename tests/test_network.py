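"""Network assembly: nodes, typed edges, filtering, the simple view."""

import pytest

from codenet.document import CodeDocument, GlossaryEntry, Provision, census
from codenet.network import (
    BuildOptions,
    CodeNetwork,
    DanglingReferenceError,
    build_network,
    filter_network,
    simple_view,
)
from codenet.refs import Kind, ProvisionRef, make_ref
from codenet.synthetic import SyntheticSpec, generate_code


def test_single_article_no_glossary():
    doc = CodeDocument()
    doc.articles = [Provision(make_ref((1,)), body="no citations at all")]
    net = build_network(doc)
    assert net.n_nodes == 2  # preamble + article
    assert net.edge_census().get("crossref", 0) == 0
    net2 = build_network(doc, BuildOptions(include_preamble=False))
    assert net2.n_nodes == 1


def test_repeated_citation_aggregates_weight(two_article_doc):
    """Art.2 citing 'Art. 1' twice -> one crossref edge of weight 2."""
    net = build_network(two_article_doc, BuildOptions(include_preamble=False))
    edges = [(u, v, k, w) for u, v, k, w in net.edges() if k == "crossref"]
    assert edges == [("Art.2", "Art.1", "crossref", 2)]


def test_structural_edges_form_parent_child_forest(two_article_doc):
    net = build_network(two_article_doc)
    structural = {(u, v) for u, v, k, _ in net.edges() if k == "structural"}
    assert structural == {("Art.1", "Art.1.1"), ("Art.1", "Art.1.2")}
    assert net.check_invariants() == []


def test_self_and_ancestor_citations_excluded():
    doc = CodeDocument()
    art = Provision(make_ref((3,)), body="see Art. 3 itself")
    art.children = [Provision(ProvisionRef(Kind.SUBARTICLE, (3, 1)),
                              body="back to Art. 3 and Art. 3.1")]
    doc.articles = [art]
    net = build_network(doc)
    assert net.edge_census().get("crossref", 0) == 0


def test_mutual_citations_merge_onto_one_edge():
    doc = CodeDocument()
    doc.articles = [
        Provision(make_ref((1,)), body="see Art. 2"),
        Provision(make_ref((2,)), body="see Art. 1"),
    ]
    net = build_network(doc)
    edges = [(u, v, w) for u, v, k, w in net.edges() if k == "crossref"]
    assert edges == [("Art.1", "Art.2", 2)]
    assert net.check_invariants() == []


def test_dangling_reference_strict_vs_lenient():
    doc = CodeDocument()
    doc.articles = [Provision(make_ref((1,)), body="see Art. 99")]
    net = build_network(doc)  # lenient: skip and log
    assert net.edge_census().get("crossref", 0) == 0
    with pytest.raises(DanglingReferenceError, match="Art.99"):
        build_network(doc, BuildOptions(strict=True))


def test_glossary_usage_edges(toy_doc):
    net = build_network(toy_doc)
    usage = [(u, v, w) for u, v, k, w in net.edges() if k == "glossary_usage"]
    assert ("Art.1", "Gloss:available name", 1) in usage
    for u, v, _ in usage:
        kinds = {net.kind_of(u), net.kind_of(v)}
        assert "glossary_term" in kinds and len(kinds) == 2
    assert net.check_invariants() == []


def test_node_count_matches_census(toy_doc):
    net = build_network(toy_doc)
    c = census(toy_doc)
    provisions = sum(n for k, n in c.by_kind.items() if k is not Kind.GLOSSARY_TERM)
    # + glossary terms + the glossary section node
    assert net.n_nodes == provisions + c[Kind.GLOSSARY_TERM] + 1


def test_filter_identity_and_removal(toy_doc):
    net = build_network(toy_doc)
    assert filter_network(net) == net
    dropped = filter_network(net, drop_kinds=["glossary_term"])
    assert dropped.n_nodes == net.n_nodes - 2
    assert dropped.edge_census().get("glossary_usage", 0) == 0
    assert filter_network(net, drop_kinds=[k for k in
                                           {d["kind"] for _, d in net.nodes()}]).n_nodes == 0


def test_simple_view_sums_types_and_directions():
    net = CodeNetwork()
    net.add_node("a", "article")
    net.add_node("b", "glossary_term")
    net.add_edge("a", "b", "crossref", 2)
    net.add_edge("a", "b", "glossary_usage", 1)
    g = simple_view(net)
    assert g.number_of_edges() == 1
    assert g["a"]["b"]["weight"] == 3
    # idempotence: a simple net is its own simple view
    assert simple_view(net).edges == g.edges
    assert g.number_of_edges() <= net.n_edges


def test_build_is_deterministic(toy_doc, tmp_path):
    from codenet.graphio import write_graph

    n1, n2 = build_network(toy_doc), build_network(toy_doc)
    p1, p2 = tmp_path / "a.gexf", tmp_path / "b.gexf"
    write_graph(n1, p1)
    write_graph(n2, p2)
    assert p1.read_bytes() == p2.read_bytes()


@pytest.mark.parametrize("seed", range(10))
def test_builder_reproduces_planted_ground_truth(seed):
    """Extraction + builder recover the planted network edge for edge."""
    doc, truth = generate_code(SyntheticSpec(n_articles=8, n_glossary=15, seed=seed))
    assert build_network(doc) == truth
    assert truth.check_invariants() == []
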