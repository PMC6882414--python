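"""Preview the reach of an amendment and of a deletion.

The k-degree ego network of a provision bounds what an amendment to it can
touch: first degree = everything it cites, is cited by, or shares
vocabulary with; second degree = everything those touch.
"""

from codenet import build_network, ego, generate_code
from codenet.impact import amendment_impact, deletion_preview
from codenet.synthetic import SyntheticSpec

doc, _ = generate_code(SyntheticSpec(n_articles=30, n_glossary=60, seed=42))
net = build_network(doc)

print(ego(net, ["Art.5"], 1).summary())
# n nodes at k=1: the provisions/terms directly entangled with Art.5

print()
_, narrative = amendment_impact(net, [8, 9, 10], 2)
print(narrative)
# second-degree reach usually spans most of the network: shared glossary
# vocabulary bridges otherwise distant provisions

print()
print(deletion_preview(net, "Art.5").summary())
# the edge delta equals Art.5's simple-view degree; components tell whether
# the deletion disconnects anything
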