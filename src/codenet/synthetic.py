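"""Synthetic code documents with known ground-truth networks.

The generator emits a complete code document — numbered articles with
dotted sub-articles, lettered recommendations, examples, a glossary and
appendices — whose bodies contain literally rendered cross-reference
phrases and glossary terms. Because every planted phrase is recorded, the
exact network the extractor and builder *should* produce is returned
alongside the document, so the whole pipeline can be verified edge for
edge without any real code text.

Default parameters emulate the scale of the zoological nomenclature code:
90 articles carrying roughly 750 sub-articles, ~130 recommendations and
examples, 333 glossary terms, three appendices, and reference/usage rates
that give a network of roughly 1,400 nodes and 10,000+ edges with
preferential-attachment hubs.

What the generator does *not* emulate: real legal prose (bodies are
nonsense filler), implicit references ("the Principle above"), and
transcription noise — ground truth is unambiguous by construction, so
passing round-trip tests demonstrates extractor/builder correctness, not
robustness to messy transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .document import ChapterSpan, CodeDocument, GlossaryEntry, Provision
from .network import CodeNetwork
from .refs import Kind, ProvisionRef, make_ref

__all__ = ["SyntheticSpec", "SpecError", "generate_code", "CODE_SCALE_SPEC"]


class SpecError(ValueError):
    """Infeasible generator specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic code generator.

    All counts are non-negative, probabilities lie in [0, 1], and the
    output is fully determined by ``seed``.
    """

    n_articles: int = 90
    max_depth: int = 3            # articles are depth 1; sub-articles below
    mean_children: float = 2.45   # Poisson mean of sub-articles per unit
    rec_rate: float = 1.4         # Poisson mean of recommendations per article
    example_rate: float = 0.15    # Poisson mean of examples per provision
    n_glossary: int = 333
    n_appendices: int = 3
    ref_density: float = 2.5      # expected planted references per provision
    hub_bias: float = 0.7         # preferential-attachment strength in [0, 1]
    glossary_usage_rate: float = 6.5  # expected planted term occurrences per provision
    variant_fraction: float = 0.3     # glossary entries given an explicit variant
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles < 0 or self.n_glossary < 0 or self.n_appendices < 0:
            raise SpecError("counts must be non-negative")
        if not (0.0 <= self.hub_bias <= 1.0):
            raise SpecError("hub_bias must lie in [0, 1]")
        if not (0.0 <= self.variant_fraction <= 1.0):
            raise SpecError("variant_fraction must lie in [0, 1]")
        if min(self.mean_children, self.rec_rate, self.example_rate,
               self.ref_density, self.glossary_usage_rate) < 0:
            raise SpecError("rates must be non-negative")
        if self.max_depth < 1:
            raise SpecError("max_depth must be at least 1")
        if self.ref_density > 0 and self.n_articles < 2:
            raise SpecError("references require at least two articles")
        if self.glossary_usage_rate > 0 and self.n_glossary == 0:
            raise SpecError("glossary usage requires glossary terms")


#: the study-scale configuration used by the acceptance analyses
CODE_SCALE_SPEC = SyntheticSpec()


# ----------------------------------------------------------------------
# vocabulary
# ----------------------------------------------------------------------

# filler lexicon: no digits, no reference keywords, no "the glossary/preamble"
_FILLER = (
    "name", "names", "taxon", "work", "type", "species", "genus", "family",
    "author", "rank", "act", "case", "usage", "valid", "senior", "junior",
    "original", "subsequent", "fixation", "designation", "publication",
    "spelling", "emendation", "holotype", "lectotype", "neotype", "syntype",
    "must", "may", "when", "under", "after", "before", "such", "which",
    "applies", "formed", "treated", "deemed", "available", "proposed",
)

_SYLLABLES = ("va", "kre", "zun", "dor", "mib", "tal", "qor", "fen",
              "lux", "pra", "gos", "nyl", "sev", "bru", "chi", "wep")


def _coin_word(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        k = int(rng.integers(2, 4))
        word = "".join(_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), k))
        if word not in taken and word not in _FILLER:
            taken.add(word)
            return word


def _filler(rng: np.random.Generator, n: int) -> list[str]:
    return [_FILLER[int(i)] for i in rng.integers(0, len(_FILLER), n)]


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def generate_code(spec: SyntheticSpec) -> tuple[CodeDocument, CodeNetwork]:
    """Generate a document and the ground-truth network it must yield.

    The ground truth is assembled from the *planting record* — every
    reference phrase and glossary occurrence written into a body — using
    the same published conventions the builder follows (self and ancestor
    citations dropped, weights aggregated, structural containment edges,
    preamble/appendix/glossary-section nodes included). Running extraction
    and :func:`codenet.network.build_network` with default options on the
    returned document reproduces the returned network exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    doc = CodeDocument(edition=f"synthetic edition (seed {spec.seed})")
    doc.preamble = Provision(ProvisionRef(Kind.PREAMBLE), "Preamble",
                             " ".join(_filler(rng, 25)))

    # --- structure ----------------------------------------------------
    def grow(path: tuple[int, ...], depth: int) -> Provision:
        prov = Provision(make_ref(path), title=" ".join(_filler(rng, 2)).title())
        if depth < spec.max_depth:
            for i in range(int(rng.poisson(spec.mean_children))):
                prov.children.append(grow(path + (i + 1,), depth + 1))
        if path and len(path) == 1:
            n_recs = int(rng.poisson(spec.rec_rate))
            for j in range(min(n_recs, 26)):
                ref = ProvisionRef(Kind.RECOMMENDATION, path, letter=chr(ord("A") + j))
                prov.children.append(Provision(ref, title=" ".join(_filler(rng, 2)).title()))
        if int(rng.poisson(spec.example_rate)) > 0:
            ref = ProvisionRef(Kind.EXAMPLE, path, ordinal=1)
            prov.children.append(Provision(ref))
        return prov

    for num in range(1, spec.n_articles + 1):
        doc.articles.append(grow((num,), 1))
    for i in range(1, spec.n_appendices + 1):
        doc.appendices.append(
            Provision(ProvisionRef(Kind.APPENDIX, (i,)),
                      title=" ".join(_filler(rng, 2)).title(),
                      body=" ".join(_filler(rng, 20))))

    # --- glossary -----------------------------------------------------
    taken: set[str] = set()
    for _ in range(spec.n_glossary):
        term = f"{_coin_word(rng, taken)} {_coin_word(rng, taken)}"
        variants = []
        if rng.random() < spec.variant_fraction:
            variants.append(f"{_coin_word(rng, taken)} {_coin_word(rng, taken)}")
        doc.glossary.append(GlossaryEntry(term, " ".join(_filler(rng, 10)), variants))

    provisions = [p for p in doc.provisions()]
    citable = [p.ref for p in provisions
               if p.ref.kind in (Kind.ARTICLE, Kind.SUBARTICLE,
                                 Kind.RECOMMENDATION, Kind.EXAMPLE)]
    citable_idx = {r: i for i, r in enumerate(citable)}
    node_ids = {p.ref.canonical for p in provisions}
    article_nums = [a.ref.path[0] for a in doc.articles]

    planted_refs: dict[tuple[str, str], int] = {}
    planted_terms: dict[tuple[str, str], int] = {}
    # preferential-attachment weights: attractiveness = citations + a small
    # baseline, so early random hits snowball into hubs
    _PA_BASELINE = 0.25
    cite_counts = np.full(len(citable), _PA_BASELINE)
    term_counts = np.full(max(len(doc.glossary), 1), _PA_BASELINE)

    def pick_target(source: ProvisionRef) -> ProvisionRef:
        if rng.random() < spec.hub_bias:
            probs = cite_counts / cite_counts.sum()
            idx = int(rng.choice(len(citable), p=probs))
        else:
            idx = int(rng.integers(0, len(citable)))
        return citable[idx]

    def record_ref(source: ProvisionRef, target: ProvisionRef) -> None:
        """Apply the builder's conventions to the planting record."""
        if target.canonical not in node_ids and not (
                target.kind is Kind.GLOSSARY_SECTION and doc.glossary):
            return
        if target == source or target.is_ancestor_of(source):
            return
        key = (source.canonical, target.canonical)
        planted_refs[key] = planted_refs.get(key, 0) + 1
        if target in citable_idx:
            cite_counts[citable_idx[target]] += 1

    def render_single(target: ProvisionRef) -> str:
        dotted = ".".join(map(str, target.path))
        if target.kind is Kind.ARTICLE:
            return str(rng.choice([f"Art. {dotted}", f"Article {dotted}",
                                   f"art. {dotted}", f"Art.{dotted}"]))
        if target.kind is Kind.SUBARTICLE:
            return str(rng.choice([f"Art. {dotted}", f"Article {dotted}"]))
        if target.kind is Kind.RECOMMENDATION:
            return str(rng.choice([f"Rec. {dotted}{target.letter}",
                                   f"Recommendation {dotted}{target.letter}"]))
        if target.kind is Kind.EXAMPLE:
            return f"Example of Art. {dotted}"
        if target.kind is Kind.APPENDIX:
            return f"Appendix {chr(ord('A') + target.path[0] - 1)}"
        if target.kind is Kind.GLOSSARY_SECTION:
            return "the Glossary"
        if target.kind is Kind.PREAMBLE:
            return "the Preamble"
        raise AssertionError(target)

    def make_phrases(source: ProvisionRef) -> list[str]:
        phrases: list[str] = []
        n_refs = int(rng.poisson(spec.ref_density))
        for _ in range(n_refs):
            roll = rng.random()
            if roll < 0.08 and len(article_nums) >= 3:
                # comma/and list of articles
                nums = sorted(int(n) for n in rng.choice(
                    article_nums, size=min(3, len(article_nums)), replace=False))
                for n in nums:
                    record_ref(source, make_ref((n,)))
                phrases.append(f"Arts. {nums[0]}, {nums[1]} and {nums[2]}")
            elif roll < 0.16 and len(article_nums) >= 2:
                # consecutive range, article granularity
                lo = int(rng.integers(article_nums[0], article_nums[-1]))
                hi = min(lo + int(rng.integers(1, 4)), article_nums[-1])
                if hi <= lo:
                    continue
                for n in range(lo, hi + 1):
                    record_ref(source, make_ref((n,)))
                dash = str(rng.choice(["-", "–"]))
                phrases.append(f"Arts. {lo}{dash}{hi}")
            elif roll < 0.20 and spec.n_appendices:
                t = ProvisionRef(Kind.APPENDIX, (int(rng.integers(1, spec.n_appendices + 1)),))
                record_ref(source, t)
                phrases.append(render_single(t))
            elif roll < 0.24 and doc.glossary:
                t = ProvisionRef(Kind.GLOSSARY_SECTION)
                record_ref(source, t)
                phrases.append(render_single(t))
            elif roll < 0.26:
                t = ProvisionRef(Kind.PREAMBLE)
                record_ref(source, t)
                phrases.append(render_single(t))
            else:
                t = pick_target(source)
                record_ref(source, t)
                phrases.append(render_single(t))
        n_terms = int(rng.poisson(spec.glossary_usage_rate)) if doc.glossary else 0
        for _ in range(n_terms):
            if rng.random() < spec.hub_bias:
                probs = term_counts / term_counts.sum()
                ti = int(rng.choice(len(doc.glossary), p=probs))
            else:
                ti = int(rng.integers(0, len(doc.glossary)))
            entry = doc.glossary[ti]
            term_counts[ti] += 1
            surface = entry.term
            roll = rng.random()
            if entry.variants and roll < 0.3:
                surface = entry.variants[0]
            elif roll < 0.5:
                surface = surface + "s"          # rule-generated plural
            key = (source.canonical, entry.term)
            planted_terms[key] = planted_terms.get(key, 0) + 1
            phrases.append(surface)
        order = rng.permutation(len(phrases))
        return [phrases[int(i)] for i in order]

    def assemble_body(phrases: list[str]) -> str:
        words = _filler(rng, int(rng.integers(3, 8)))
        for phrase in phrases:
            words.append(phrase)
            words.extend(_filler(rng, int(rng.integers(2, 7))))
        return " ".join(words)

    for prov in provisions:
        if prov.ref.kind is Kind.APPENDIX:
            continue  # appendix bodies stay plain filler
        prov.body = assemble_body(make_phrases(prov.ref))

    # a few glossary definitions cite an article (definition crossrefs)
    for entry in doc.glossary:
        if article_nums and rng.random() < 0.15:
            t = make_ref((int(rng.choice(article_nums)),))
            record_ref(entry.ref, t)
            entry.definition = f"{entry.definition} see {render_single(t)}"

    # --- chapters (metadata only; builder default leaves them out) -----
    if spec.n_articles >= 10:
        bounds = np.linspace(1, spec.n_articles + 1, 7, dtype=int)
        for i in range(len(bounds) - 1):
            doc.chapters.append(ChapterSpan(i + 1, f"Chapter {i + 1}",
                                            int(bounds[i]), int(bounds[i + 1]) - 1))

    return doc, _ground_truth(doc, planted_refs, planted_terms)


def _ground_truth(doc: CodeDocument,
                  planted_refs: dict[tuple[str, str], int],
                  planted_terms: dict[tuple[str, str], int]) -> CodeNetwork:
    """Assemble the expected network directly from the planting record."""
    net = CodeNetwork(directed=True)
    for prov in doc.provisions():
        label = prov.ref.canonical if not prov.title else f"{prov.ref.canonical} {prov.title}"
        net.add_node(prov.ref.canonical, prov.ref.kind.value, label,
                     len(prov.body.split()))
    if doc.glossary:
        net.add_node("Glossary", Kind.GLOSSARY_SECTION.value, "Glossary", 0)
    for entry in doc.glossary:
        net.add_node(entry.ref.canonical, Kind.GLOSSARY_TERM.value, entry.term,
                     len(entry.definition.split()))
    for prov in doc.provisions():
        parent = prov.ref.parent
        if parent is not None and parent.canonical in net.g:
            net.add_edge(parent.canonical, prov.ref.canonical, "structural")
    for (src, dst), count in planted_refs.items():
        net.add_edge(src, dst, "crossref", count)
    for (src, term), count in planted_terms.items():
        net.add_edge(src, f"Gloss:{term}", "glossary_usage", count)
    return net
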