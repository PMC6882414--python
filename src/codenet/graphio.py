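"""Reading and writing code networks in standard graph formats.

Formats: GEXF 1.2 (primary exchange format, readable by Gephi), GraphML,
edge-list CSV (``source,target,type,weight`` — loses node kinds, documented
here) and node-link graph JSON. GEXF, GraphML and graph JSON round-trip
node kinds, labels, word counts and edge weights exactly.

Networks exported by other tools (e.g. a Gephi project exported to GEXF)
use their own attribute names; :func:`read_graph` takes an attribute map
so node kinds and edge types can be recovered from whatever the file
calls them.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path

import networkx as nx

from .network import CodeNetwork

__all__ = ["read_graph", "write_graph", "FORMATS"]

logger = logging.getLogger(__name__)

FORMATS = ("gexf", "graphml", "csv", "json")

_SUFFIXES = {".gexf": "gexf", ".graphml": "graphml", ".csv": "csv", ".json": "json"}

#: default attribute names used in files written by this package
DEFAULT_ATTR_MAP = {"kind": "kind", "label": "label",
                    "word_count": "word_count", "type": "type", "weight": "weight"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
        return fmt
    try:
        return _SUFFIXES[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer graph format from suffix {path.suffix!r}")


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def write_graph(net: CodeNetwork, path, fmt: str | None = None) -> None:
    """Write a network; the format is inferred from the suffix unless given.

    All writers are byte-deterministic for a fixed input network (the GEXF
    meta date is pinned so repeated exports are identical).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "gexf":
        # GEXF reserves 'type' on edge elements (directedness); export the
        # edge type under a safe attvalue name so parallel typed edges survive
        export = nx.MultiDiGraph()
        export.add_nodes_from(net.g.nodes(data=True))
        for u, v, k, d in net.g.edges(keys=True, data=True):
            export.add_edge(u, v, key=k, edge_type=d["type"], weight=d["weight"])
        lines = list(nx.generate_gexf(export))
        text = "\n".join(
            re.sub(r'lastmodifieddate="[^"]*"', 'lastmodifieddate="1970-01-01"', ln)
            for ln in lines
        )
        path.write_text(text + "\n")
    elif fmt == "graphml":
        text = "\n".join(nx.generate_graphml(net.g))
        path.write_text(text + "\n")
    elif fmt == "json":
        data = nx.node_link_data(net.g, edges="edges")
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "type", "weight"])
            for u, v, k, w in net.edges():
                writer.writerow([u, v, k, w])


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------

def read_graph(path, fmt: str | None = None,
               attr_map: dict[str, str] | None = None) -> CodeNetwork:
    """Read a network from GEXF, GraphML, edge-list CSV or graph JSON.

    ``attr_map`` maps the model's attribute roles (``kind``, ``label``,
    ``word_count``, ``type``, ``weight``) to the attribute names used in
    the file, for files produced by other tools. Nodes missing a kind get
    ``"unknown"``; edges missing a weight get weight 1 with a warning;
    edges missing a type are treated as plain cross-references.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    amap = {**DEFAULT_ATTR_MAP, **(attr_map or {})}

    if fmt == "csv":
        return _read_csv(path)
    if fmt == "gexf":
        g = nx.read_gexf(path)
    elif fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
    else:
        data = json.loads(path.read_text())
        g = nx.node_link_graph(data, edges="edges")

    net = CodeNetwork(directed=g.is_directed())
    for node_id, data in g.nodes(data=True):
        net.add_node(
            str(node_id),
            kind=str(data.get(amap["kind"], "unknown")),
            label=str(data.get(amap["label"], data.get("label", str(node_id)))),
            word_count=int(data.get(amap["word_count"], 0)),
        )
    warned = False
    edge_iter = (g.edges(keys=True, data=True) if g.is_multigraph()
                 else ((u, v, None, d) for u, v, d in g.edges(data=True)))
    for u, v, key, data in edge_iter:
        etype = data.get(amap["type"], data.get("edge_type"))
        if etype is None:
            etype = key if isinstance(key, str) and not str(key).isdigit() else "crossref"
        weight = data.get(amap["weight"])
        if weight is None:
            if not warned:
                logger.warning("%s: edges carry no %r attribute; defaulting weight to 1",
                               path.name, amap["weight"])
                warned = True
            weight = 1
        net.add_edge(str(u), str(v), str(etype), int(round(float(weight))))
    return net


def _read_csv(path: Path) -> CodeNetwork:
    net = CodeNetwork(directed=True)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"source", "target"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path.name}: edge-list CSV needs source,target columns")
        if "weight" not in reader.fieldnames:
            logger.warning("%s: no weight column; defaulting weights to 1", path.name)
        for lineno, row in enumerate(reader, start=2):
            try:
                u, v = row["source"], row["target"]
                etype = row.get("type") or "crossref"
                weight = int(row.get("weight") or 1)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path.name}:{lineno}: bad edge row {row!r}") from exc
            for node in (u, v):
                if node not in net.g:
                    # CSV carries no node attributes: kinds are lost (documented)
                    net.add_node(node, kind="unknown", label=node)
            net.add_edge(u, v, etype, weight)
    return net
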