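# Methods

## The document model

A code document is a rooted forest of provisions plus a flat glossary.
Provision identity is a *canonical ref string*: `Preamble`, `Art.23`,
`Art.74.7.3`, `Rec.40A`, `Ex.51.2#1`, `App.B`, `Ch.4`, `Gloss:nomen
nudum`, and `Glossary` for the glossary section as a whole. These strings
are the node identifiers in every export, so graph files diff cleanly.
Design choices that the source material leaves open:

* Examples are unnumbered in code texts; they get positional ordinals
  (`Ex.51.2#1` is the first example under 74.7.3-style provision 51.2).
* The preamble and each appendix are single provisions without internal
  numbering.
* Chapters are metadata (article ranges), not part of the numbering tree;
  the builder can optionally emit chapter nodes, default off, because a
  published network's node total generally cannot be decomposed into one
  fixed convention.
* Word counts split on Unicode whitespace with punctuation attached; only
  self-consistency matters, no tokenizer is implied.

Two input dialects compile to the same model: a canonical JSON dialect
(schema in `src/codenet/schema/`; `serialize_document` emits it
deterministically, so parse∘serialize is the identity and re-serialization
is byte-identical) and a lightweight indented-text dialect for fixtures
and transcripts.

## Extraction

Cross-references are recognised by a fixed, documented regex grammar
(table in `codenet/extraction.py`): single refs in several spellings
(`Art. 23.1`, `Article 8`, `art.23`), comma/`and` lists, ranges at article
granularity only (`Arts. 7–9`; dotted endpoints invalidate the run —
sub-article ranges are not attested in this genre), recommendations,
`Example of Art. X` (resolving to the first example), appendices, `the
Glossary` and `the Preamble`. Overlapping candidate spans resolve
leftmost-longest, so the example phrase suppresses the bare article span
inside it. There is deliberately no statistical NLP and no resolution of
implicit references ("the Principle above"): every edge must be traceable
to a literal span.

Glossary matching compiles canonical terms, explicit variants and
rule-generated inflections (final-word `-s`, `-es`, `-y`→`-ies`) into one
longest-first alternation matched case-insensitively on word boundaries;
scanning is non-overlapping, so "unavailable name" suppresses the "name"
nested in it. The suffix rules are declared defaults, auditable and
deterministic, not a lemmatizer.

## Network construction

One node per provision and glossary entry; optional preamble, appendix,
chapter and glossary-section nodes (defaults: on, on, off, on). Edges are
stored directed (citing → cited, user → term) with at most one edge per
unordered pair and type; a reverse citation accumulates onto the existing
edge. Self-references and references to a provision's own ancestors are
dropped — the containment chain already links them, and the analyses run
loop-free. Citations inside glossary definitions become term → provision
crossref edges; term-in-definition occurrences are *not* emitted as
glossary-usage edges, because a usage edge is defined as having exactly
one glossary endpoint. Dangling references are skipped with a debug log,
or raised under `strict`. Weights are raw mention counts — no tf-idf or
normalisation, since "weighted degree" in this field means counts.

All metrics run on the undirected simple view (per-pair weight sums).
Closeness uses the component-normalised form c_i = r_i/Σd; betweenness is
unnormalised Brandes with each unordered pair counted once; path
statistics are BFS hop counts on the giant component (mean over reachable
ordered pairs, diameter = max eccentricity). Hop distances are the
substantive choice: "the user consults three more parts of the code" is a
hop statement. Weighted-distance variants sit behind a `weighted` flag and
are not used by any headline number. Rankings break ties lexicographically
on the canonical ref so output is deterministic.

The degree-tail exponent is estimated descriptively: the k ≥ 1 histogram
is log-binned (≈12 geometric bins, counts divided by bin width) and the
log-density regressed on log-k by least squares over a declared range.
`fit_range="tail"` starts the range at the histogram mode, which is the
right choice for humped distributions whose rising bulk is not
power-law-like. Graphs with fewer than 10 distinct degree values (e.g.
regular graphs) raise a fit-not-applicable error. A maximum-likelihood
power-law test is out of scope; the diagnostic claim is only "decreasing
heavy log-log tail, α > 1".

## Impact analysis and sub-codes

The k-degree ego network of a seed set is the BFS ball of radius k with
its induced edges. Coverage fractions use the whole network's N and E as
denominators, glossary included — a published percentage computed on an
undocumented smaller base cannot be reverse-engineered, so the base is
fixed and stated. Amendment reach seeds every node belonging to the
amended articles (article + descendants by default; an `whole_article`
switch restricts to the article nodes, since announcements rarely say
which granularity is meant). Glossary terms are never implicit seeds.
Deletion previews are pure: neighbourhoods are reported on the intact
network, then N, E, density and components are recomputed on a copy with
the node removed.

Sub-code extraction takes the k-ball (k ≤ 2) of topic seeds, adds
ancestors of members as *context-only* headers (they do not recursively
pull their other children — that keeps subsets small and autonomous),
includes glossary entries whose node is a member, and renders everything
in original document order with a provenance header. The k-ball rule is a
declared default; no claim is made that any published subset used the same
rule.

## The synthetic generator

`generate_code` emits a document plus the exact network it must yield.
Structure: articles with Poisson(2.45) children to depth 3,
recommendations Poisson(1.4) per article, examples Poisson(0.15) per
provision, three appendices. Scale defaults emulate the zoological
nomenclature code: 90 articles (≈750 sub-articles, ≈120 recommendations
and examples), 333 glossary terms, >51,000 words, giving ≈1,400 nodes and
≈11,000 edges. Reference phrases (2.5 per provision, all grammar dialects
sampled) pick targets by mixed preferential attachment: with probability
`hub_bias` (default 0.7) proportional to citations-so-far plus a 0.25
baseline attractiveness, else uniformly; glossary usage (6.5 occurrences
per provision) works the same over terms. The baseline of 0.25 makes early
random hits snowball into hubs, reproducing the hub-dominated, heavy-tailed
degree structure such codes show; `hub_bias=0` recovers uniform targeting.

Glossary terms are two-word nonsense tokens with globally unique words, so
matches are unambiguous and ground truth is exact by construction; filler
text contains no digits, no reference keywords and no term words. The
ground-truth network is assembled from the planting record, not by running
the extractor, so round-trip equality is a genuine two-route check.

What the generator does **not** emulate: real legal prose, implicit or
malformed references, transcription noise, and the real code's specific
topology beyond scale and hubbiness. Passing round-trip tests therefore
demonstrates extractor/builder correctness on well-formed text, not
robustness to messy transcripts; and descriptor values measured on
synthetic networks characterise the emulation, not any real code.

## I/O and determinism

GEXF 1.2 is the primary exchange format; GraphML and node-link JSON also
round-trip kinds, labels, word counts and typed weights exactly, and
edge-list CSV round-trips edges but loses node kinds. GEXF reserves the
edge attribute name `type` for directedness, so the edge type is exported
as an `edge_type` attvalue; the reader accepts both. The GEXF meta date is
pinned to a constant so all writers are byte-deterministic. Files from
other tools load via an attribute map (`{"kind": "Type"}` etc.); missing
weights default to 1 with a warning. The native binary `.gephi` project
container is not parsed — export such projects to GEXF first.

## Problem sizes used by the test and acceptance runs

Brute-force oracle suites use 200 random graphs with N ≤ 12 (all-pairs
BFS, exhaustive shortest-path enumeration) and 100 synthetic codes of 8
articles; the study-scale analyses (acceptance script, qualitative tests)
use the full 90-article/333-term configuration, on which generation,
build and the complete descriptor set take well under a minute on one
core.

## Known limitations

* Reference recall is bounded by the declared grammar; a transcript using
  unanticipated citation styles needs grammar extension.
* Glossary inflection rules cover English plurals only.
* The power-law fit is descriptive; no goodness-of-fit hypothesis test.
* Community / thematic-area detection and force-directed layout are out of
  scope; networks are exported for external layout tools.
* Multi-edition (historical) comparison is not implemented.
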