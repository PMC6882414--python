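"""Per-node and whole-network descriptors of a code network.

All descriptors run on the undirected weighted *simple view* (see
:func:`codenet.network.simple_view`) and, unless stated otherwise, use
unweighted hop distances: a path length of 3 means "three more parts of the
code to consult". Weighted-distance variants of closeness, betweenness and
the path statistics exist behind the ``weighted`` flag, treating each
edge's weight as a traversal cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import CodeNetwork, simple_view

__all__ = [
    "MetricsReport",
    "FitNotApplicableError",
    "PowerLawFit",
    "degree_metrics",
    "clustering",
    "closeness",
    "betweenness",
    "path_stats",
    "density",
    "degree_distribution",
    "power_law_fit",
    "compute_metrics",
    "rank_nodes",
]


def _as_simple(net) -> nx.Graph:
    if isinstance(net, CodeNetwork):
        return simple_view(net)
    if isinstance(net, nx.Graph) and not net.is_directed() and not net.is_multigraph():
        return net
    raise TypeError(f"expected CodeNetwork or simple undirected nx.Graph, got {type(net)}")


class FitNotApplicableError(ValueError):
    """Degree distribution too degenerate for a power-law fit."""


# ----------------------------------------------------------------------
# per-node metrics
# ----------------------------------------------------------------------

def degree_metrics(net) -> pd.DataFrame:
    """Degree (neighbour count) and weighted degree (sum of incident
    simple-view weights) per node."""
    g = _as_simple(net)
    ids = list(g.nodes)
    return pd.DataFrame(
        {
            "degree": [g.degree(n) for n in ids],
            "weighted_degree": [g.degree(n, weight="weight") for n in ids],
        },
        index=pd.Index(ids, name="node"),
    )


def clustering(net) -> pd.Series:
    """Local clustering coefficient C_i = 2 t_i / (k_i (k_i - 1)).

    C_i = 1 means the node's neighbourhood is fully interconnected; nodes
    with fewer than two neighbours get C_i = 0.
    """
    g = _as_simple(net)
    return pd.Series(nx.clustering(g), name="clustering").reindex(list(g.nodes))


def closeness(net, harmonic: bool = False, weighted: bool = False) -> pd.Series:
    """Closeness centrality c_i = r_i / (sum of distances to the r_i
    reachable nodes), normalised within components.

    ``harmonic=True`` returns instead the sum of reciprocal distances
    (robust on disconnected networks).
    """
    g = _as_simple(net)
    dist = "weight" if weighted else None
    if harmonic:
        vals = nx.harmonic_centrality(g, distance=dist)
    else:
        vals = nx.closeness_centrality(g, distance=dist, wf_improved=False)
    return pd.Series(vals, name="closeness").reindex(list(g.nodes))


def betweenness(net, normalized: bool = False, weighted: bool = False) -> pd.Series:
    """Shortest-path betweenness: for each node, the sum over node pairs of
    the fraction of shortest paths passing through it (unnormalised by
    default; each unordered pair counted once)."""
    g = _as_simple(net)
    vals = nx.betweenness_centrality(
        g, normalized=normalized, weight="weight" if weighted else None)
    return pd.Series(vals, name="betweenness").reindex(list(g.nodes))


# ----------------------------------------------------------------------
# global descriptors
# ----------------------------------------------------------------------

def path_stats(net, weighted: bool = False) -> dict:
    """Mean shortest-path length, diameter and component census.

    Paths are BFS hop counts on the largest connected component (averaged
    over reachable ordered pairs); the diameter is the maximum
    eccentricity there. Component counts and sizes are reported alongside.
    """
    g = _as_simple(net)
    if g.number_of_nodes() == 0:
        raise ValueError("path statistics are undefined on an empty graph")
    components = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    giant = g.subgraph(max(nx.connected_components(g), key=lambda c: (len(c), sorted(c))))
    dist = "weight" if weighted else None
    if giant.number_of_nodes() > 1:
        mean_len = nx.average_shortest_path_length(giant, weight=dist)
        diameter = nx.diameter(giant, weight=dist) if weighted else nx.diameter(giant)
    else:
        mean_len, diameter = 0.0, 0
    return {
        "mean_path_length": mean_len,
        "diameter": diameter,
        "n_components": len(components),
        "component_sizes": components,
        "giant_size": components[0],
    }


def density(net) -> float:
    """Simple-view density 2E / (N (N - 1)); undefined for N < 2."""
    g = _as_simple(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density is undefined for fewer than two nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def degree_distribution(net) -> dict[int, int]:
    """Histogram of node degree over k >= 1 (isolates excluded)."""
    g = _as_simple(net)
    hist: dict[int, int] = {}
    for _, k in g.degree():
        if k >= 1:
            hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares log-log fit of the degree histogram tail."""

    alpha: float          # exponent: frequency ~ k^(-alpha)
    k_min: int
    k_max: int
    r_squared: float
    n_points: int

    def is_heavy_tailed(self) -> bool:
        """Decreasing log-log tail steeper than 1/k — the scale-free diagnostic."""
        return self.alpha > 1.0


def power_law_fit(net, fit_range: tuple[int, int] | str | None = None,
                  min_distinct: int = 10, n_bins: int = 12) -> PowerLawFit:
    """Estimate the degree-distribution exponent by log-log regression.

    The degree histogram is log-binned (geometric bin edges, counts divided
    by bin width) and ``log10(density) ~ -alpha * log10(k)`` is fit by least
    squares over the declared range — log binning tames the noisy raw tail,
    where most degrees occur once. ``fit_range="tail"`` declares the range
    from the histogram mode upward, for humped degree distributions whose
    rising part is not power-law-like. This is a descriptive diagnostic of
    a heavy tail, not a maximum-likelihood power-law test.

    Raises
    ------
    FitNotApplicableError
        If fewer than ``min_distinct`` distinct degree values are observed
        (e.g. on a regular graph).
    """
    hist = degree_distribution(net)
    if len(hist) < min_distinct:
        raise FitNotApplicableError(
            f"only {len(hist)} distinct degree values; need >= {min_distinct}")
    if fit_range == "tail":
        # declared tail range: from the histogram mode upward — appropriate
        # for humped distributions where only the tail is power-law-like
        mode = max(hist, key=lambda k: (hist[k], -k))
        fit_range = (mode, max(hist))
    elif fit_range is None:
        fit_range = (min(hist), max(hist))
    degrees = [k for k, c in hist.items() for _ in range(c)
               if fit_range[0] <= k <= fit_range[1]]
    edges = np.unique(np.round(np.logspace(
        np.log10(fit_range[0]), np.log10(fit_range[1] + 1), n_bins)).astype(int))
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:].astype(float))
    occupied = counts > 0
    if occupied.sum() < 3:
        raise FitNotApplicableError("fewer than 3 occupied log bins in the fit range")
    x = np.log10(centers[occupied])
    y = np.log10(counts[occupied] / widths[occupied])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return PowerLawFit(alpha=-float(slope), k_min=fit_range[0], k_max=fit_range[1],
                       r_squared=r2, n_points=int(occupied.sum()))


# ----------------------------------------------------------------------
# the full report
# ----------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-node metric table plus global descriptors of one network."""

    per_node: pd.DataFrame
    global_stats: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_node.to_csv(path)

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))  # pragma: no cover
        text = json.dumps(self.global_stats, indent=2, sort_keys=True, default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compute_metrics(net, fit_power_law: bool = False) -> MetricsReport:
    """Compute the full per-node table and global descriptors.

    The per-node table holds degree, weighted degree, clustering, closeness
    and betweenness (hop-based, unnormalised betweenness) plus the node
    kind; global statistics cover counts, density, components, mean path
    length, diameter and the degree histogram. A power-law tail fit is
    attached when requested and applicable.
    """
    g = _as_simple(net)
    table = degree_metrics(g)
    table["clustering"] = clustering(g)
    table["closeness"] = closeness(g)
    table["betweenness"] = betweenness(g)
    table["kind"] = [g.nodes[n].get("kind", "unknown") for n in table.index]
    stats: dict = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    if g.number_of_nodes() >= 2:
        stats["density"] = density(g)
    if g.number_of_nodes() >= 1:
        ps = path_stats(g)
        stats.update({k: ps[k] for k in
                      ("mean_path_length", "diameter", "n_components", "giant_size")})
    stats["degree_histogram"] = degree_distribution(g)
    if fit_power_law:
        try:
            fit = power_law_fit(g)
            stats["power_law"] = {
                "alpha": fit.alpha, "k_min": fit.k_min, "k_max": fit.k_max,
                "r_squared": fit.r_squared, "n_points": fit.n_points,
            }
        except FitNotApplicableError as exc:
            stats["power_law"] = {"error": str(exc)}
    return MetricsReport(per_node=table, global_stats=stats)


def rank_nodes(report: MetricsReport, metric: str, k: int,
               kind: str | None = None) -> list[tuple[str, float]]:
    """Top-k nodes by a per-node metric, optionally restricted to one kind.

    Descending by metric value; ties broken by canonical node string, so
    rankings are deterministic.
    """
    if metric not in report.per_node.columns:
        raise KeyError(f"unknown metric {metric!r}; have {list(report.per_node.columns)}")
    table = report.per_node
    if kind is not None:
        table = table[table["kind"] == kind]
    ordered = sorted(table[metric].items(), key=lambda kv: (-kv[1], kv[0]))
    return [(node, float(val)) for node, val in ordered[: max(k, 0)]]
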