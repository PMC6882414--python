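# codenet

Network analysis of cross-referenced code texts — rulebooks such as the
codes of biological nomenclature, whose provisions cite each other and
share a defined vocabulary so densely that the text behaves less like a
book than like a small-world network.

`codenet` turns a hierarchically numbered code — a preamble, numbered
articles with dotted sub-articles (74.7.3), lettered recommendations
(40A), examples, a glossary of defined terms, appendices — into a typed,
weighted graph, and answers the questions practitioners of such codes
actually ask: *which provision is most central? how many parts of the code
must I consult on average? what can an amendment to Articles 8–10 touch?
what would deleting one sub-article disconnect? which provisions make up a
self-contained sub-code for one topic?*

## The model

Every structural unit and every glossary term is a node. Three edge types
connect them:

* **structural** — parent → child containment (weight 1), a forest;
* **crossref** — explicit citation ("Art. 23.1", "Arts. 7–9", "Rec. 40A",
  "the Glossary"), weight = mention count;
* **glossary_usage** — provision → term for each occurrence of a defined
  term in running text, weight = occurrence count.

Analyses run on the undirected *simple view* (types collapsed per node
pair, weights summed) with unweighted hop distances. Per-node descriptors
are degree *k_i*, weighted degree *s_i*, local clustering
*C_i = 2t_i / k_i(k_i−1)*, closeness *c_i = r_i / Σ_j d(i,j)* and
Brandes betweenness *b_i = Σ_{s<t} σ_st(i)/σ_st*. Global descriptors are
density *2E/N(N−1)*, component census, mean shortest-path length *L* and
diameter *D* on the giant component, and a log-binned least-squares
estimate of the degree-tail exponent α (heavy-tail / scale-free
diagnostic). Ego networks (*k*-hop balls with induced edges) quantify
amendment reach and deletion impact.

Because real code texts are copyrighted, the package ships a first-class
synthetic generator: it emits a full code document whose bodies contain
literally planted reference phrases and glossary terms, together with the
exact network they must produce — so the whole pipeline is verified
edge-for-edge against known ground truth.

## Worked example

```python
from codenet import build_network, compute_metrics, generate_code, rank_nodes
from codenet.synthetic import SyntheticSpec

doc, _ = generate_code(SyntheticSpec(n_articles=30, n_glossary=60, seed=42))
net = build_network(doc)
report = compute_metrics(net, fit_power_law=True)
```

Running `python examples/02_build_and_metrics.py` (exactly this analysis)
prints:

```
nodes: 387, edges: 3188, density: 0.0427
mean path length: 2.32 hops (consult ~2 more units on average)
diameter: 4 hops (worst case)

top 3 by degree (most-connected units):
  Gloss:brupra mibgos: 167 neighbours
  Gloss:krenylpra dornyl: 91 neighbours
  Gloss:goszunchi mibluxqor: 76 neighbours
```

Read: the network is sparse (4 % of possible connections), yet any unit is
within 4 hops of any other and 2.32 on average — a user following the
network needs to consult only a couple of further provisions to settle a
question. The most-connected nodes are glossary terms: the defined
vocabulary is what stitches distant provisions together. The other
examples (`examples/0*.py`) walk through parsing, ego/impact analysis,
sub-code extraction and the ground-truth round trip.

A thin CLI wraps the same calls:

```
codenet build mycode.txt -o net.gexf     # document -> typed GEXF network
codenet metrics net.gexf --json stats.json
codenet ego net.gexf --seed Art.55.5 --k 1
codenet impact net.gexf --articles 8,9,10,21,78 --k 2
codenet subset mycode.txt --seed Art.23 --k 1 --topic priority
codenet simulate --seed 7                # synthetic code + ground truth
codenet convert net.gexf net.graphml
```

Networks exported by other tools (e.g. Gephi GEXF exports) load through
`read_graph(path, attr_map={"kind": "Type"})`, mapping whatever attribute
names the file uses onto node kinds and edge weights.

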