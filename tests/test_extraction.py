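"""The reference grammar and the glossary matcher."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codenet.document import GlossaryEntry
from codenet.extraction import (
    GlossaryMatcher,
    extract_references,
    match_glossary,
)


def hits(body):
    return [(h.target.canonical, h.count) for h in extract_references(body)]


@pytest.mark.parametrize(
    "body, expected",
    [
        ("amended Art. 74.7.3", [("Art.74.7.3", 1)]),
        ("see Article 8 for details", [("Art.8", 1)]),
        ("Arts. 36, 43, 46 deal with typification",
         [("Art.36", 1), ("Art.43", 1), ("Art.46", 1)]),
        ("Arts. 36, 43 and 46", [("Art.36", 1), ("Art.43", 1), ("Art.46", 1)]),
        ("Arts. 7–9 on publication", [("Art.7", 1), ("Art.8", 1), ("Art.9", 1)]),
        ("Arts. 7-9", [("Art.7", 1), ("Art.8", 1), ("Art.9", 1)]),
        ("Rec. 40A applies", [("Rec.40A", 1)]),
        ("see Recommendation 73F", [("Rec.73F", 1)]),
        ("the Example of Art. 51.2 shows", [("Ex.51.2#1", 1)]),
        ("listed in Appendix B", [("App.B", 1)]),
        ("defined in the Glossary", [("Glossary", 1)]),
        ("stated in the Preamble", [("Preamble", 1)]),
        ("ART. 23.1 shouts", [("Art.23.1", 1)]),       # case-insensitive
        ("Art.23.1 without space", [("Art.23.1", 1)]),
        ("no reference phrases here", []),
        ("", []),
    ],
)
def test_reference_grammar(body, expected):
    assert hits(body) == expected


def test_duplicates_aggregate_in_first_appearance_order():
    body = "Art. 2 then Art. 1 then Art. 2 again"
    assert hits(body) == [("Art.2", 2), ("Art.1", 1)]


def test_example_phrase_suppresses_inner_article():
    """Leftmost-longest: the example reference wins over its inner Art. span."""
    assert hits("per the Example of Art. 51.2 and Art. 3") == [
        ("Ex.51.2#1", 1), ("Art.3", 1)]


def test_subarticle_ranges_not_expanded():
    """Ranges expand at article granularity only; dotted endpoints are ignored."""
    assert hits("Arts. 7.1-9 are odd") == []


@given(st.sampled_from([
    "Art. 23.1", "Arts. 3, 5 and 9", "Rec. 40A", "Appendix C", "the Glossary",
]), st.integers(0, 5), st.integers(0, 5))
@settings(max_examples=60, derandomize=True)
def test_extraction_idempotent_and_whitespace_insensitive(phrase, left, right):
    body = " " * left + phrase + " " * right
    first = extract_references(body)
    assert extract_references(body) == first
    assert extract_references(phrase) == first


# ----------------------------------------------------------------------
# glossary matching
# ----------------------------------------------------------------------

def test_empty_glossary_matches_nothing():
    assert match_glossary("any text with names and taxa", []) == []


def test_leftmost_longest_wins(toy_glossary):
    """'unavailable name' suppresses the bare 'name' nested inside it."""
    out = match_glossary("a nomen nudum is an unavailable name", toy_glossary)
    assert [(h.term, h.count) for h in out] == [
        ("nomen nudum", 1), ("unavailable name", 1)]


def test_case_and_inflection_matching(toy_glossary):
    out = match_glossary("Names, NAME and more names; unavailable names too",
                         toy_glossary)
    assert dict((h.term, h.count) for h in out) == {
        "name": 3, "unavailable name": 1}


def test_variants_map_to_canonical():
    glossary = [GlossaryEntry("available name", variants=["availability"])]
    out = match_glossary("availability is key to an available name", glossary)
    assert [(h.term, h.count) for h in out] == [("available name", 2)]


def test_y_plural_rule():
    glossary = [GlossaryEntry("family-group entity", variants=["synonymy"])]
    out = match_glossary("two synonymies were found", glossary)
    assert [(h.term, h.count) for h in out] == [("family-group entity", 1)]


def _naive_quadratic_count(body, surfaces):
    """Oracle: scan every position, take the longest surface starting there."""
    words_lower = body.casefold()
    total = 0
    i = 0
    while i < len(body):
        if i > 0 and (body[i - 1].isalnum() or body[i - 1] == "_"):
            i += 1
            continue
        best = 0
        for s in surfaces:
            if words_lower.startswith(s, i):
                end = i + len(s)
                boundary = end == len(body) or not (body[end].isalnum() or body[end] == "_")
                if boundary and len(s) > best:
                    best = len(s)
        if best:
            total += 1
            i += best
        else:
            i += 1
    return total


@pytest.mark.parametrize("body", [
    "a nomen nudum is an unavailable name",
    "name names name unavailable name nomen nudum",
    "no terms at all in this sentence",
    "NAME, and a nomen nudum; also names galore",
])
def test_total_hits_match_quadratic_oracle(body, toy_glossary):
    matcher = GlossaryMatcher(toy_glossary)
    got = sum(h.count for h in matcher.hits(body))
    surfaces = sorted(matcher.surface_to_term, key=len, reverse=True)
    assert got == _naive_quadratic_count(body, surfaces)
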