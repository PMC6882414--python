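"""Extract a topical sub-code and render it as continuous text.

Seeds one article, expands one degree through the network, and re-emits
the selected provisions (with their governing articles as context
headers) in original order — a self-contained mini-code for one topic.
"""

from codenet import build_network, extract_subcode, generate_code, render_subcode
from codenet.synthetic import SyntheticSpec

doc, _ = generate_code(SyntheticSpec(n_articles=12, n_glossary=15, seed=7))
net = build_network(doc)

sub = extract_subcode(doc, net, ["Art.4"], k=1, topic="everything around Art.4")
print(f"{len(sub.provisions)} provisions, {len(sub.glossary)} glossary entries, "
      f"{len(sub.context_refs)} context-only headers\n")
print(render_subcode(sub)[:1200])
# [context] lines are structural headers only; their other children were
# not pulled in, keeping the subset small and autonomous
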