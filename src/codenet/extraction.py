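"""Detection of cross-references and glossary-term usage in provision text.

These two extractors create the non-structural edges of the code network:
explicit citations of other provisions ("Art. 23.1", "Arts. 7-9",
"Rec. 40A", "the Glossary") and occurrences of defined glossary terms in
running text. Both are deterministic, regex-based and auditable; there is
no statistical NLP here by design — every edge must be traceable to a
literal span of text.

Reference grammar (case-insensitive):

=========================  ==========================================
pattern                    resolves to
=========================  ==========================================
``Art. 23.1`` / ``Article 8``   article or dotted sub-article
``Arts. 36, 43 and 46``         one hit per listed article
``Arts. 7-9`` (hyphen/en-dash)  expanded range, article granularity only
``Rec. 40A`` / ``Recommendation 73F``  lettered recommendation
``Example of Art. 51.2``        the (first) Example under that provision
``Appendix B``                  appendix
``the Glossary``                the glossary section node
``the Preamble``                the preamble node
=========================  ==========================================
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .document import GlossaryEntry
from .refs import Kind, ProvisionRef, make_ref

__all__ = ["ReferenceHit", "TermHit", "extract_references", "match_glossary", "GlossaryMatcher"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceHit:
    """One cited provision with its aggregated mention count in a body."""

    target: ProvisionRef
    count: int


@dataclass(frozen=True)
class TermHit:
    """One glossary term with its occurrence count in a body."""

    term: str
    count: int


# ----------------------------------------------------------------------
# cross-reference grammar
# ----------------------------------------------------------------------

_DOTTED = r"\d+(?:\.\d+)*"
# a run of article numbers: "36, 43 and 46", "7-9", "23.1"
_NUMRUN = rf"{_DOTTED}(?:\s*[–-]\s*\d+)?(?:\s*(?:,|,?\s+and)\s+{_DOTTED}(?:\s*[–-]\s*\d+)?)*"

_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("example", re.compile(
        rf"\bExamples?\s+of\s+Art(?:icle)?s?\.?\s*({_DOTTED})", re.I)),
    ("recommendation", re.compile(
        r"\bRec(?:ommendation)?s?\.?\s*(\d+)\s*([A-Za-z])\b", re.I)),
    ("article", re.compile(
        rf"\bArt(?:icle)?s?\.?\s*({_NUMRUN})", re.I)),
    ("appendix", re.compile(r"\bAppendix\s+([A-Z])\b", re.I)),
    ("glossary", re.compile(r"\bthe\s+Glossary\b", re.I)),
    ("preamble", re.compile(r"\bthe\s+Preamble\b", re.I)),
]

_RANGE_RE = re.compile(rf"^({_DOTTED})\s*[–-]\s*(\d+)$")


def _expand_numrun(run: str) -> list[ProvisionRef] | None:
    """Expand "36, 43 and 46" / "7-9" / "23.1" into provision refs.

    Ranges expand at article granularity only; a dotted endpoint makes the
    whole run unparseable (returns None, the near-match is logged).
    """
    refs: list[ProvisionRef] = []
    parts = re.split(r"(?:,|,?\s+and)\s+", run.strip())
    for part in parts:
        part = part.strip()
        m = _RANGE_RE.match(part)
        if m:
            lo_txt, hi_txt = m.groups()
            if "." in lo_txt:
                return None  # sub-article ranges are not attested
            lo, hi = int(lo_txt), int(hi_txt)
            if hi < lo or hi - lo > 200:
                return None
            refs.extend(make_ref((n,)) for n in range(lo, hi + 1))
        else:
            refs.append(make_ref(tuple(int(p) for p in part.split("."))))
    return refs


def extract_references(body: str) -> list[ReferenceHit]:
    """Find explicit cross-references in a body of text.

    Returns aggregated hits in order of first appearance. Overlapping
    candidate spans are resolved leftmost-longest, so "Example of Art. 51.2"
    yields the example ref, not a bare Art. 51.2 hit. Unparseable
    near-matches are ignored and logged at DEBUG level.
    """
    spans: list[tuple[int, int, list[ProvisionRef]]] = []
    for name, pattern in _PATTERNS:
        for m in pattern.finditer(body):
            refs: list[ProvisionRef] | None
            if name == "example":
                path = tuple(int(p) for p in m.group(1).split("."))
                refs = [ProvisionRef(Kind.EXAMPLE, path, ordinal=1)]
            elif name == "recommendation":
                refs = [ProvisionRef(Kind.RECOMMENDATION, (int(m.group(1)),),
                                     letter=m.group(2).upper())]
            elif name == "article":
                refs = _expand_numrun(m.group(1))
                if refs is None:
                    logger.debug("ignoring unparseable reference %r", m.group(0))
                    continue
            elif name == "appendix":
                refs = [ProvisionRef(Kind.APPENDIX, (ord(m.group(1)) - ord("A") + 1,))]
            elif name == "glossary":
                refs = [ProvisionRef(Kind.GLOSSARY_SECTION)]
            else:
                refs = [ProvisionRef(Kind.PREAMBLE)]
            spans.append((m.start(), m.end(), refs))
    # leftmost-longest, non-overlapping
    spans.sort(key=lambda s: (s[0], -s[1]))
    chosen: list[list[ProvisionRef]] = []
    cursor = -1
    for start, end, refs in spans:
        if start >= cursor:
            chosen.append(refs)
            cursor = end
    counts: dict[ProvisionRef, int] = {}
    order: list[ProvisionRef] = []
    for refs in chosen:
        for ref in refs:
            if ref not in counts:
                counts[ref] = 0
                order.append(ref)
            counts[ref] += 1
    return [ReferenceHit(ref, counts[ref]) for ref in order]


# ----------------------------------------------------------------------
# glossary term matching
# ----------------------------------------------------------------------

def _inflections(surface: str) -> set[str]:
    """Deterministic suffix-rule inflections of a surface form.

    Pluralises the final word: ``-s``, ``-es``, and ``-y`` -> ``-ies``.
    No lemmatizer — the rules are declared, auditable defaults.
    """
    forms = {surface}
    head, _, last = surface.rpartition(" ")
    prefix = head + " " if head else ""
    forms.add(prefix + last + "s")
    forms.add(prefix + last + "es")
    if last.endswith("y") and len(last) > 1:
        forms.add(prefix + last[:-1] + "ies")
    return forms


class GlossaryMatcher:
    """Precompiled, case-insensitive, leftmost-longest glossary matcher.

    Canonical terms, their explicit variants and rule-generated plural
    inflections are compiled into one alternation ordered longest-first;
    scanning is non-overlapping, so a span matched by a longer term
    suppresses any shorter term inside it ("unavailable name" beats "name").
    """

    def __init__(self, glossary: list[GlossaryEntry]):
        self.surface_to_term: dict[str, str] = {}
        for entry in glossary:
            for base in [entry.term, *entry.variants]:
                for form in _inflections(base.casefold()):
                    # first owner wins; validate_document flags ambiguity
                    self.surface_to_term.setdefault(form, entry.term)
        if self.surface_to_term:
            alternation = "|".join(
                re.escape(s).replace(r"\ ", r"\s+")
                for s in sorted(self.surface_to_term, key=len, reverse=True)
            )
            self._pattern: re.Pattern | None = re.compile(
                rf"\b(?:{alternation})\b", re.I)
        else:
            self._pattern = None

    def hits(self, body: str) -> list[TermHit]:
        if self._pattern is None:
            return []
        counts: dict[str, int] = {}
        order: list[str] = []
        for m in self._pattern.finditer(body):
            surface = re.sub(r"\s+", " ", m.group(0).casefold())
            term = self.surface_to_term[surface]
            if term not in counts:
                counts[term] = 0
                order.append(term)
            counts[term] += 1
        return [TermHit(term, counts[term]) for term in order]


def match_glossary(body: str, glossary: list[GlossaryEntry]) -> list[TermHit]:
    """Count glossary-term occurrences in a body (leftmost-longest).

    Convenience wrapper compiling the glossary per call; reuse a
    :class:`GlossaryMatcher` when scanning many bodies.
    """
    return GlossaryMatcher(glossary).hits(body)
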