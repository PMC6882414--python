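"""Topic-specific sub-codes: ordered, self-contained extracts of a code.

A sub-code is built by picking seed provisions for a topic, expanding
through the network (k-hop ego ball), closing structurally upward so every
included sub-article keeps its governing article as a context header, and
re-emitting everything in the original document order as continuous text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .document import CodeDocument, GlossaryEntry, Provision
from .impact import ego
from .network import CodeNetwork
__all__ = ["SubCode", "extract_subcode", "render_subcode"]


class EmptySubsetError(ValueError):
    """The expansion produced no provisions."""


@dataclass
class SubCode:
    """An ordered topical extract of a code document.

    ``context_refs`` marks provisions included only as structural headers
    (ancestors of true members); they do not pull in their other children.
    """

    topic: str
    seeds: tuple[str, ...]
    k: int
    provisions: list[Provision] = field(default_factory=list)
    glossary: list[GlossaryEntry] = field(default_factory=list)
    context_refs: frozenset[str] = frozenset()

    @property
    def refs(self) -> list[str]:
        return [p.ref.canonical for p in self.provisions]


def extract_subcode(doc: CodeDocument, net: CodeNetwork, seeds, k: int,
                    topic: str = "") -> SubCode:
    """Extract the sub-code for a topic from its seed provisions.

    Members are the k-hop ego ball of the seeds on the network's simple
    view; glossary entries join when their node is a member; ancestors of
    any member are added as context-only headers. Output order is the
    source document's order.
    """
    if k not in (0, 1, 2):
        raise ValueError("k must be 0, 1 or 2 for sub-code extraction")
    report = ego(net, seeds, k)
    member_ids = set(report.members)

    prov_map = doc.provision_map()
    gloss_map = doc.glossary_map()

    wanted: set[str] = set()
    context: set[str] = set()
    for mid in member_ids:
        if mid in prov_map:
            wanted.add(mid)
            ref = prov_map[mid].ref
            parent = ref.parent
            while parent is not None:
                pid = parent.canonical
                if pid in prov_map and pid not in wanted:
                    context.add(pid)
                parent = parent.parent
    context -= wanted
    if not wanted:
        raise EmptySubsetError(f"no provisions selected by seeds {list(seeds)!r}")

    ordered = [p for p in doc.provisions() if p.ref.canonical in wanted | context]
    glossary = [gloss_map[t] for t in sorted(gloss_map)
                if f"Gloss:{t}" in member_ids]
    return SubCode(
        topic=topic,
        seeds=report.seeds,
        k=k,
        provisions=ordered,
        glossary=glossary,
        context_refs=frozenset(context),
    )


def render_subcode(sub: SubCode) -> str:
    """Render a sub-code as deterministic continuous text.

    A provenance header records the topic, seeds and expansion rule; each
    provision keeps its original numbering; context-only headers are
    marked. Rendering the sub-code of the full node set re-emits every
    provision of the document in order.
    """
    if not sub.provisions:
        raise EmptySubsetError("cannot render an empty sub-code")
    lines = [
        f"# Sub-code: {sub.topic or 'untitled topic'}",
        f"# seeds: {', '.join(sub.seeds)}",
        f"# expansion: {sub.k}-degree ego ball, structural closure to headers",
        "",
    ]
    for prov in sub.provisions:
        tag = " [context]" if prov.ref.canonical in sub.context_refs else ""
        title = f" {prov.title}" if prov.title else ""
        lines.append(f"{prov.ref.canonical}.{title}{tag}")
        if prov.body and prov.ref.canonical not in sub.context_refs:
            lines.append(prov.body)
        lines.append("")
    if sub.glossary:
        lines.append("Glossary.")
        for entry in sub.glossary:
            lines.append(f"  {entry.term} = {entry.definition}")
        lines.append("")
    return "\n".join(lines)
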