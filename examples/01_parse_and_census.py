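"""Parse a small code text and take its census.

Builds a six-line toy code in the indented dialect, parses it and prints
how many units of each kind it contains — the first thing to check when a
transcript of a real code is loaded.
"""

from codenet import census, parse_document, serialize_document

TOY = """\
!edition: worked example
Preamble. Scope
  This code governs the naming of toy animals.
Article 1. Availability
  An available name is one that is published, see Art. 2.
  1.1. Publication
    Printed or electronic works count.
Article 2. Validity
  The valid name is the oldest available name, per Art. 1.
Glossary.
  available name = a name satisfying Article 1
  valid name = the correct available name
"""

doc = parse_document(TOY)
c = census(doc)
for kind, count in sorted(c.by_kind.items(), key=lambda kv: kv[0].value):
    print(f"{kind.value:>14}: {count}")
print(f"{'words':>14}: {c.words}")
# Each unit becomes a network node later; the word count sizes the corpus.

print("\ncanonical JSON round-trips:",
      parse_document(serialize_document(doc)) == doc)
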