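"""Canonical identifiers for structural units of a code text.

Every provision of a hierarchically numbered code — an article, a dotted
sub-article, a lettered recommendation, an example, the preamble, an
appendix — and every glossary term is addressed by a :class:`ProvisionRef`.
The canonical string form (``Art.74.7.3``, ``Rec.40A``, ``Gloss:nomen
nudum``) is the node identifier used throughout the package, so exported
graph files are diffable and human-readable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import total_ordering


class Kind(str, Enum):
    """Kinds of structural units a code text is decomposed into."""

    PREAMBLE = "preamble"
    CHAPTER = "chapter"
    ARTICLE = "article"
    SUBARTICLE = "subarticle"
    RECOMMENDATION = "recommendation"
    EXAMPLE = "example"
    GLOSSARY_TERM = "glossary_term"
    GLOSSARY_SECTION = "glossary_section"
    APPENDIX = "appendix"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RefError(ValueError):
    """Raised for malformed provision references."""


# kinds addressed purely by a dotted number path
_PATH_KINDS = {
    Kind.CHAPTER,
    Kind.ARTICLE,
    Kind.SUBARTICLE,
    Kind.RECOMMENDATION,
    Kind.EXAMPLE,
    Kind.APPENDIX,
}
# kinds that are singleton sections without numbering
_SECTION_KINDS = {Kind.PREAMBLE, Kind.GLOSSARY_SECTION}

_APPENDIX_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@total_ordering
@dataclass(frozen=True)
class ProvisionRef:
    """Canonical identifier of one structural unit of a code.

    Parameters
    ----------
    kind
        The structural kind (article, subarticle, recommendation, ...).
    path
        Dotted numbering as a tuple of positive integers, e.g. ``(74, 7, 3)``
        for sub-article 74.7.3. Empty for the preamble, the glossary section
        and glossary terms.
    letter
        Uppercase letter suffix for recommendations (``Rec.40A`` has
        ``path=(40,)``, ``letter="A"``).
    term
        Normalised term string, glossary terms only.
    ordinal
        Position (1-based) distinguishing several Examples attached to the
        same provision; examples are unnumbered in code texts.
    """

    kind: Kind
    path: tuple[int, ...] = ()
    letter: str | None = None
    term: str | None = None
    ordinal: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Kind(self.kind))
        object.__setattr__(self, "path", tuple(int(p) for p in self.path))
        k = self.kind
        if any(p <= 0 for p in self.path):
            raise RefError(f"non-positive component in path {self.path}")
        if k is Kind.GLOSSARY_TERM:
            if not self.term or self.path:
                raise RefError("glossary_term refs carry a term and no path")
        elif k in _SECTION_KINDS:
            if self.path or self.term:
                raise RefError(f"{k.value} refs carry neither path nor term")
        else:
            if self.term or not self.path:
                raise RefError(f"{k.value} refs carry a non-empty path and no term")
        if k is Kind.ARTICLE and len(self.path) != 1:
            raise RefError(f"article refs have a single-component path, got {self.path}")
        if k is Kind.SUBARTICLE and len(self.path) < 2:
            raise RefError(f"subarticle refs have path length >= 2, got {self.path}")
        if k in (Kind.CHAPTER, Kind.APPENDIX, Kind.RECOMMENDATION) and len(self.path) != 1:
            raise RefError(f"{k.value} refs have a single-component path, got {self.path}")
        if k is Kind.RECOMMENDATION:
            if not (self.letter and self.letter.isalpha() and self.letter.isupper()):
                raise RefError(f"recommendation refs need an uppercase letter, got {self.letter!r}")
        elif self.letter is not None:
            raise RefError(f"{k.value} refs carry no letter")
        if k is Kind.EXAMPLE:
            if not self.ordinal or self.ordinal < 1:
                raise RefError("example refs need a positive ordinal")
        elif self.ordinal is not None:
            raise RefError(f"{k.value} refs carry no ordinal")

    # ------------------------------------------------------------------
    @property
    def canonical(self) -> str:
        """Unique canonical string form; ``parse`` round-trips it."""
        k = self.kind
        dotted = ".".join(str(p) for p in self.path)
        if k is Kind.PREAMBLE:
            return "Preamble"
        if k is Kind.GLOSSARY_SECTION:
            return "Glossary"
        if k is Kind.GLOSSARY_TERM:
            return f"Gloss:{self.term}"
        if k is Kind.CHAPTER:
            return f"Ch.{dotted}"
        if k in (Kind.ARTICLE, Kind.SUBARTICLE):
            return f"Art.{dotted}"
        if k is Kind.RECOMMENDATION:
            return f"Rec.{dotted}{self.letter}"
        if k is Kind.EXAMPLE:
            return f"Ex.{dotted}#{self.ordinal}"
        if k is Kind.APPENDIX:
            return f"App.{_APPENDIX_LETTERS[self.path[0] - 1]}"
        raise AssertionError(k)

    def __str__(self) -> str:
        return self.canonical

    def __lt__(self, other: "ProvisionRef") -> bool:
        return self.sort_key() < other.sort_key()

    def sort_key(self) -> tuple:
        """Document order: preamble, articles (with attachments), glossary, appendices."""
        band = {
            Kind.PREAMBLE: 0,
            Kind.CHAPTER: 1,
            Kind.ARTICLE: 1,
            Kind.SUBARTICLE: 1,
            Kind.RECOMMENDATION: 1,
            Kind.EXAMPLE: 1,
            Kind.GLOSSARY_SECTION: 2,
            Kind.GLOSSARY_TERM: 2,
            Kind.APPENDIX: 3,
        }[self.kind]
        # within one governing provision: the provision, its examples,
        # then recommendations, then deeper sub-articles follow naturally
        tail = (
            0 if self.kind not in (Kind.EXAMPLE, Kind.RECOMMENDATION) else
            1 if self.kind is Kind.EXAMPLE else 2,
            self.ordinal or 0,
            self.letter or "",
            self.term or "",
        )
        return (band, self.path, tail)

    # ------------------------------------------------------------------
    def is_ancestor_of(self, other: "ProvisionRef") -> bool:
        """True if ``other`` is numbered under this provision (strictly)."""
        if self.kind not in (Kind.ARTICLE, Kind.SUBARTICLE, Kind.CHAPTER):
            return False
        if other.kind is Kind.GLOSSARY_TERM or not other.path:
            return False
        if self.kind is Kind.CHAPTER:
            return False  # chapters group articles by range, not by path prefix
        if len(other.path) < len(self.path):
            return False
        if other.path[: len(self.path)] == self.path:
            return other != self
        return False

    @property
    def parent(self) -> "ProvisionRef | None":
        """The governing provision ref, or None for top-level units."""
        k = self.kind
        if k in (Kind.RECOMMENDATION, Kind.EXAMPLE):
            return make_ref(self.path)
        if k is Kind.SUBARTICLE:
            return make_ref(self.path[:-1])
        return None

    @classmethod
    def parse(cls, text: str) -> "ProvisionRef":
        """Parse a canonical string form back into a ref."""
        s = text.strip()
        if s == "Preamble":
            return cls(Kind.PREAMBLE)
        if s == "Glossary":
            return cls(Kind.GLOSSARY_SECTION)
        if s.startswith("Gloss:"):
            return cls(Kind.GLOSSARY_TERM, term=s[len("Gloss:"):])
        m = re.fullmatch(r"Ch\.(\d+)", s)
        if m:
            return cls(Kind.CHAPTER, (int(m.group(1)),))
        m = re.fullmatch(r"Art\.(\d+(?:\.\d+)*)", s)
        if m:
            return make_ref(tuple(int(p) for p in m.group(1).split(".")))
        m = re.fullmatch(r"Rec\.(\d+)([A-Z]+)", s)
        if m:
            return cls(Kind.RECOMMENDATION, (int(m.group(1)),), letter=m.group(2))
        m = re.fullmatch(r"Ex\.(\d+(?:\.\d+)*)#(\d+)", s)
        if m:
            path = tuple(int(p) for p in m.group(1).split("."))
            return cls(Kind.EXAMPLE, path, ordinal=int(m.group(2)))
        m = re.fullmatch(r"App\.([A-Z])", s)
        if m:
            return cls(Kind.APPENDIX, (_APPENDIX_LETTERS.index(m.group(1)) + 1,))
        raise RefError(f"cannot parse provision ref {text!r}")


def make_ref(path: tuple[int, ...] | list[int]) -> ProvisionRef:
    """Article or sub-article ref from a dotted number path."""
    path = tuple(path)
    kind = Kind.ARTICLE if len(path) == 1 else Kind.SUBARTICLE
    return ProvisionRef(kind, path)


def article_ref(num: int) -> ProvisionRef:
    return ProvisionRef(Kind.ARTICLE, (num,))


def glossary_ref(term: str) -> ProvisionRef:
    return ProvisionRef(Kind.GLOSSARY_TERM, term=term)
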