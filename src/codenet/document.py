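"""Parsing, validation and serialization of structured code documents.

A *code document* is a hierarchically numbered rule text: a preamble, a
sequence of numbered articles carrying dotted sub-articles, lettered
recommendations and unnumbered examples, a glossary of defined terms, and
appendices. Two input dialects are supported:

* a canonical JSON dialect (schema shipped in ``codenet/schema/``) — the
  format written by :func:`serialize_document`;
* a lightweight indented-text dialect for hand-written fixtures and
  transcripts, compiled to the same model.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .refs import Kind, ProvisionRef, make_ref

__all__ = [
    "Provision",
    "GlossaryEntry",
    "ChapterSpan",
    "CodeDocument",
    "Violation",
    "StructureError",
    "Census",
    "parse_document",
    "serialize_document",
    "validate_document",
    "census",
]


class StructureError(ValueError):
    """Malformed document structure (bad numbering, duplicate refs, ...)."""


@dataclass
class Provision:
    """One structural unit with its text and ordered children."""

    ref: ProvisionRef
    title: str = ""
    body: str = ""
    children: list["Provision"] = field(default_factory=list)

    def walk(self):
        """Yield this provision and all descendants in document order."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class GlossaryEntry:
    """A defined term with its definition and surface-form variants."""

    term: str
    definition: str = ""
    variants: list[str] = field(default_factory=list)

    @property
    def ref(self) -> ProvisionRef:
        return ProvisionRef(Kind.GLOSSARY_TERM, term=self.term)


@dataclass
class ChapterSpan:
    """Optional chapter metadata: a label grouping a closed range of articles."""

    num: int
    title: str = ""
    first_article: int = 0
    last_article: int = 0

    @property
    def ref(self) -> ProvisionRef:
        return ProvisionRef(Kind.CHAPTER, (self.num,))


@dataclass
class CodeDocument:
    """A parsed code: preamble, articles, glossary, appendices, metadata."""

    preamble: Provision = field(
        default_factory=lambda: Provision(ProvisionRef(Kind.PREAMBLE))
    )
    articles: list[Provision] = field(default_factory=list)
    glossary: list[GlossaryEntry] = field(default_factory=list)
    appendices: list[Provision] = field(default_factory=list)
    edition: str = ""
    amendments: list[str] = field(default_factory=list)
    chapters: list[ChapterSpan] = field(default_factory=list)

    def provisions(self):
        """All provisions (preamble, article trees, appendices) in order."""
        yield self.preamble
        for art in self.articles:
            yield from art.walk()
        yield from self.appendices

    def provision_map(self) -> dict[str, Provision]:
        return {p.ref.canonical: p for p in self.provisions()}

    def glossary_map(self) -> dict[str, GlossaryEntry]:
        return {e.term: e for e in self.glossary}


@dataclass(frozen=True)
class Violation:
    """One invariant violation: the offending ref and the broken rule."""

    ref: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ref}: {self.rule} ({self.detail})" if self.detail else f"{self.ref}: {self.rule}"


# ----------------------------------------------------------------------
# parsing — canonical JSON dialect
# ----------------------------------------------------------------------

def parse_document(source: str) -> CodeDocument:
    """Parse a code document from JSON or indented-text source.

    The dialect is auto-detected: sources whose first non-blank character
    is ``{`` are read as the canonical JSON dialect, everything else as the
    indented-text dialect.

    Raises
    ------
    StructureError
        On malformed numbering (a child whose number does not extend its
        parent) or duplicate provision refs, naming the offending unit.
    """
    stripped = source.lstrip()
    if stripped.startswith("{"):
        doc = _parse_json(stripped)
    else:
        doc = _parse_indented(source)
    _check_structure(doc)
    return doc


def _parse_json(text: str) -> CodeDocument:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:  # pragma: no cover - message passthrough
        raise StructureError(f"invalid JSON: {exc}") from exc
    meta = data.get("metadata", {})
    doc = CodeDocument(
        edition=meta.get("edition", ""),
        amendments=list(meta.get("amendments", [])),
        chapters=[
            ChapterSpan(c["num"], c.get("title", ""), c["first_article"], c["last_article"])
            for c in meta.get("chapters", [])
        ],
    )
    pre = data.get("preamble", {})
    doc.preamble = Provision(
        ProvisionRef(Kind.PREAMBLE), pre.get("title", ""), pre.get("body", "")
    )
    for art in data.get("articles", []):
        doc.articles.append(_provision_from_json(art, parent_path=()))
    for entry in data.get("glossary", []):
        doc.glossary.append(
            GlossaryEntry(entry["term"], entry.get("definition", ""),
                          list(entry.get("variants", [])))
        )
    for i, app in enumerate(data.get("appendices", []), start=1):
        ref = ProvisionRef(Kind.APPENDIX, (i,))
        doc.appendices.append(Provision(ref, app.get("title", ""), app.get("body", "")))
    return doc


def _provision_from_json(node: dict, parent_path: tuple[int, ...]) -> Provision:
    kind = node.get("kind", "article" if not parent_path else "subarticle")
    if kind in ("article", "subarticle"):
        num = node["num"]
        path = parent_path + (int(num),)
        ref = make_ref(path)
        if (kind == "article") != (len(path) == 1):
            raise StructureError(f"kind {kind!r} inconsistent with numbering {'.'.join(map(str, path))}")
    elif kind == "recommendation":
        if len(parent_path) != 1:
            raise StructureError(
                f"recommendation {node.get('letter')!r} must attach to an article, "
                f"not {'.'.join(map(str, parent_path)) or 'top level'}"
            )
        ref = ProvisionRef(Kind.RECOMMENDATION, parent_path, letter=node["letter"])
        path = parent_path
    elif kind == "example":
        ref = ProvisionRef(Kind.EXAMPLE, parent_path, ordinal=int(node["ordinal"]))
        path = parent_path
    else:
        raise StructureError(f"unknown provision kind {kind!r}")
    prov = Provision(ref, node.get("title", ""), node.get("body", ""))
    ex_ordinal = 0
    for child in node.get("children", []):
        ckind = child.get("kind", "subarticle")
        if ckind == "example" and "ordinal" not in child:
            ex_ordinal += 1
            child = {**child, "ordinal": ex_ordinal}
        if ckind in ("article", "subarticle") and ref.kind not in (Kind.ARTICLE, Kind.SUBARTICLE):
            raise StructureError(f"{ref.canonical} cannot carry numbered children")
        prov.children.append(_provision_from_json(child, path))
    return prov


# ----------------------------------------------------------------------
# parsing — indented-text dialect
# ----------------------------------------------------------------------

_META_RE = re.compile(r"^!(\w+):\s*(.*)$")
_CHAPTER_RE = re.compile(r"^Chapter\s+(\d+)\.?\s*(.*)$", re.I)
_ARTICLE_RE = re.compile(r"^Article\s+(\d+)\.\s*(.*)$", re.I)
_SUBART_RE = re.compile(r"^(\d+(?:\.\d+)+)\.\s*(.*)$")
_REC_RE = re.compile(r"^Recommendation\s+(\d+)([A-Z])\.\s*(.*)$", re.I)
_EXAMPLE_RE = re.compile(r"^Example\.\s*(.*)$", re.I)
_APPENDIX_RE = re.compile(r"^Appendix\s+([A-Z])\.\s*(.*)$", re.I)
_GLOSS_ENTRY_RE = re.compile(r"^(.+?)(?:\s*\[([^\]]*)\])?\s*=\s*(.*)$")


def _parse_indented(source: str) -> CodeDocument:
    """Compile the lightweight indented dialect to a CodeDocument.

    Headers (``Article 1. Title``, ``74.7.3. Title``, ``Recommendation 40A.``,
    ``Example.``, ``Preamble.``, ``Glossary.``, ``Appendix A.``) may appear at
    any indentation; all other non-blank lines are body text of the most
    recent unit. Glossary entries are ``term [variant; variant] = definition``
    lines inside the ``Glossary.`` section.
    """
    doc = CodeDocument()
    current: Provision | None = None          # unit receiving body lines
    stack: list[Provision] = []               # open article/sub-article chain
    in_glossary = False
    current_entry: GlossaryEntry | None = None
    current_chapter: ChapterSpan | None = None

    def close_chapter() -> None:
        nonlocal current_chapter
        if current_chapter is not None and doc.articles:
            current_chapter.last_article = doc.articles[-1].ref.path[0]
        current_chapter = None

    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _META_RE.match(line)
        if m:
            key, value = m.groups()
            if key == "edition":
                doc.edition = value
            elif key == "amendment":
                doc.amendments.append(value)
            continue
        if line.lower() in ("preamble.", "preamble:") or line.lower().startswith("preamble."):
            current = doc.preamble
            current.title = line[len("preamble."):].strip() or current.title
            in_glossary = False
            continue
        if line.lower() in ("glossary.", "glossary:"):
            in_glossary = True
            current = None
            continue
        m = _CHAPTER_RE.match(line)
        if m:
            close_chapter()
            first = doc.articles[-1].ref.path[0] + 1 if doc.articles else 1
            current_chapter = ChapterSpan(int(m.group(1)), m.group(2).strip(), first, first)
            doc.chapters.append(current_chapter)
            in_glossary = False
            continue
        m = _APPENDIX_RE.match(line)
        if m:
            close_chapter()
            in_glossary = False
            num = ord(m.group(1).upper()) - ord("A") + 1
            prov = Provision(ProvisionRef(Kind.APPENDIX, (num,)), m.group(2).strip())
            doc.appendices.append(prov)
            current, stack = prov, []
            continue
        m = _ARTICLE_RE.match(line)
        if m:
            in_glossary = False
            prov = Provision(make_ref((int(m.group(1)),)), m.group(2).strip())
            doc.articles.append(prov)
            if current_chapter is not None:
                current_chapter.last_article = prov.ref.path[0]
            stack = [prov]
            current = prov
            continue
        m = _SUBART_RE.match(line)
        if m and not in_glossary:
            path = tuple(int(p) for p in m.group(1).split("."))
            while stack and stack[-1].ref.path != path[:-1]:
                stack.pop()
            if not stack:
                raise StructureError(
                    f"line {lineno}: sub-article {m.group(1)} has no open parent"
                )
            prov = Provision(make_ref(path), m.group(2).strip())
            stack[-1].children.append(prov)
            stack.append(prov)
            current = prov
            continue
        m = _REC_RE.match(line)
        if m and not in_glossary:
            art_num = int(m.group(1))
            host = next((a for a in doc.articles if a.ref.path == (art_num,)), None)
            if host is None:
                raise StructureError(
                    f"line {lineno}: recommendation {m.group(1)}{m.group(2)} "
                    f"attaches to missing Article {art_num}"
                )
            ref = ProvisionRef(Kind.RECOMMENDATION, (art_num,), letter=m.group(2).upper())
            prov = Provision(ref, m.group(3).strip())
            host.children.append(prov)
            current = prov
            continue
        m = _EXAMPLE_RE.match(line)
        if m and not in_glossary and stack:
            host = stack[-1]
            ordinal = 1 + sum(1 for c in host.children if c.ref.kind is Kind.EXAMPLE)
            ref = ProvisionRef(Kind.EXAMPLE, host.ref.path, ordinal=ordinal)
            prov = Provision(ref, "", m.group(1).strip())
            host.children.append(prov)
            current = prov
            continue
        if in_glossary:
            m = _GLOSS_ENTRY_RE.match(line)
            if m:
                term, variants, definition = m.groups()
                current_entry = GlossaryEntry(
                    term.strip(),
                    definition.strip(),
                    [v.strip() for v in (variants or "").split(";") if v.strip()],
                )
                doc.glossary.append(current_entry)
            elif current_entry is not None:
                current_entry.definition = (current_entry.definition + " " + line).strip()
            continue
        if current is None:
            raise StructureError(f"line {lineno}: body text before any unit: {line!r}")
        current.body = (current.body + "\n" + line).strip() if current.body else line
    close_chapter()
    return doc


# ----------------------------------------------------------------------
# structural checks shared by both dialects
# ----------------------------------------------------------------------

def _check_structure(doc: CodeDocument) -> None:
    violations = validate_document(doc)
    hard = [v for v in violations if v.rule in ("duplicate-ref", "bad-child-path", "articles-not-increasing")]
    if hard:
        raise StructureError("; ".join(str(v) for v in hard))


def validate_document(doc: CodeDocument) -> list[Violation]:
    """Check all model invariants; returns one :class:`Violation` per breach.

    An empty list means the document is valid. Violations are data, not
    exceptions, so callers can report all problems at once.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for prov in doc.provisions():
        c = prov.ref.canonical
        if c in seen:
            out.append(Violation(c, "duplicate-ref", "provision ref appears more than once"))
        seen.add(c)
    # child numbering extends the parent by exactly one component
    for art in doc.articles:
        for prov in art.walk():
            ords: list[int] = []
            ex_ords: list[int] = []
            for child in prov.children:
                ck, pk = child.ref.kind, prov.ref.kind
                if ck is Kind.SUBARTICLE:
                    if child.ref.path[:-1] != prov.ref.path or len(child.ref.path) != len(prov.ref.path) + 1:
                        out.append(Violation(child.ref.canonical, "bad-child-path",
                                             f"does not extend parent {prov.ref.canonical}"))
                    else:
                        ords.append(child.ref.path[-1])
                elif ck in (Kind.RECOMMENDATION, Kind.EXAMPLE):
                    if child.ref.path != prov.ref.path:
                        out.append(Violation(child.ref.canonical, "bad-child-path",
                                             f"not attached to governing provision {prov.ref.canonical}"))
                    if ck is Kind.EXAMPLE:
                        ex_ords.append(child.ref.ordinal)
                    if ck is Kind.RECOMMENDATION and pk is not Kind.ARTICLE:
                        out.append(Violation(child.ref.canonical, "recommendation-host",
                                             "recommendations attach to articles"))
                else:
                    out.append(Violation(child.ref.canonical, "bad-child-kind", ck.value))
            if ords != sorted(ords) or len(ords) != len(set(ords)):
                out.append(Violation(prov.ref.canonical, "siblings-not-increasing",
                                     f"sub-article numbers {ords}"))
            if ex_ords != sorted(ex_ords) or len(ex_ords) != len(set(ex_ords)):
                out.append(Violation(prov.ref.canonical, "examples-not-increasing",
                                     f"example ordinals {ex_ords}"))
    nums = [a.ref.path[0] for a in doc.articles]
    if nums != sorted(nums) or len(nums) != len(set(nums)):
        out.append(Violation("Art.*", "articles-not-increasing", f"article numbers {nums}"))
    folded: dict[str, str] = {}
    for entry in doc.glossary:
        key = entry.term.casefold()
        if key in folded:
            out.append(Violation(entry.ref.canonical, "duplicate-term",
                                 f"case-folds with {folded[key]!r}"))
        folded[key] = entry.term
    variant_owner: dict[str, str] = {}
    for entry in doc.glossary:
        for v in entry.variants:
            key = v.casefold()
            if key in variant_owner and variant_owner[key] != entry.term:
                out.append(Violation(entry.ref.canonical, "ambiguous-variant",
                                     f"{v!r} also a variant of {variant_owner[key]!r}"))
            variant_owner[key] = entry.term
    return out


# ----------------------------------------------------------------------
# census
# ----------------------------------------------------------------------

@dataclass
class Census:
    """Counts of structural units by kind, plus the whitespace word count."""

    by_kind: dict[Kind, int]
    words: int

    def __getitem__(self, kind: Kind) -> int:
        return self.by_kind.get(Kind(kind), 0)


def census(doc: CodeDocument) -> Census:
    """Count units of each kind and whitespace-delimited words of all bodies.

    Word counting splits on Unicode whitespace with punctuation attached;
    glossary definitions count as the bodies of their terms.
    """
    by_kind: dict[Kind, int] = {}
    words = 0
    for prov in doc.provisions():
        by_kind[prov.ref.kind] = by_kind.get(prov.ref.kind, 0) + 1
        words += len(prov.body.split())
    for entry in doc.glossary:
        by_kind[Kind.GLOSSARY_TERM] = by_kind.get(Kind.GLOSSARY_TERM, 0) + 1
        words += len(entry.definition.split())
    return Census(by_kind, words)


# ----------------------------------------------------------------------
# serialization — canonical JSON
# ----------------------------------------------------------------------

def serialize_document(doc: CodeDocument) -> str:
    """Render the canonical JSON dialect; ``parse_document`` round-trips it.

    Output is deterministic (fixed key order, two-space indent, trailing
    newline), so re-serialising a parsed document is byte-identical.
    """
    data = {
        "dialect": "codenet-document",
        "version": 1,
        "metadata": {
            "edition": doc.edition,
            "amendments": list(doc.amendments),
            "chapters": [
                {"num": c.num, "title": c.title,
                 "first_article": c.first_article, "last_article": c.last_article}
                for c in doc.chapters
            ],
        },
        "preamble": {"title": doc.preamble.title, "body": doc.preamble.body},
        "articles": [_provision_to_json(a) for a in doc.articles],
        "glossary": [
            {"term": e.term, "definition": e.definition, "variants": list(e.variants)}
            for e in doc.glossary
        ],
        "appendices": [{"title": a.title, "body": a.body} for a in doc.appendices],
    }
    return json.dumps(data, indent=2, ensure_ascii=False) + "\n"


def _provision_to_json(prov: Provision) -> dict:
    ref = prov.ref
    node: dict = {"kind": ref.kind.value}
    if ref.kind in (Kind.ARTICLE, Kind.SUBARTICLE):
        node["num"] = ref.path[-1]
    elif ref.kind is Kind.RECOMMENDATION:
        node["letter"] = ref.letter
    elif ref.kind is Kind.EXAMPLE:
        node["ordinal"] = ref.ordinal
    node["title"] = prov.title
    node["body"] = prov.body
    node["children"] = [_provision_to_json(c) for c in prov.children]
    return node
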