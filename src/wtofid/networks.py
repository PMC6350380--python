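"""Unweighted networks from top-scoring gene pairs and their topology.

A hard-threshold network keeps the top fraction of gene pairs (default
0.2%) as unweighted edges; only genes incident to a retained edge become
nodes.  Summaries cover the descriptors on which correlation- and
wTO-based networks differ most: size, local clustering, degree
assortativity (negative values indicate hub-and-spoke structure), and the
Louvain community partition with its modularity.  Hub fidelity between two
networks is the overlap of their top-100-by-degree node lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .fidelity import ScoreVector

__all__ = [
    "NetworkSummary",
    "build_top_fraction_network",
    "summarize_network",
    "hub_overlap",
    "write_edge_list",
    "write_graphml",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSummary:
    """Topological descriptors of one hard-threshold network.

    ``degree_assortativity`` is None when undefined (degree-regular
    graphs leave the degree correlation 0/0); it is never fabricated as 0.
    """

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    degree_assortativity: float | None
    n_communities: int
    modularity: float
    top_hubs: list[str] = field(repr=False)
    seed: int = 0


def build_top_fraction_network(scores: ScoreVector, fraction: float) -> nx.Graph:
    """Unweighted graph of the ``round(fraction × n_pairs)`` strongest pairs.

    Ties at the boundary are broken by canonical pair order, so the edge
    set is a deterministic function of the score vector.  Nodes are only
    the genes incident to a retained edge.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_edges = round(fraction * scores.n_pairs)
    if n_edges == 0:
        raise ValueError(
            f"fraction {fraction} of {scores.n_pairs} pairs yields zero edges"
        )
    n = len(scores.gene_ids)
    idx_i, idx_j = np.triu_indices(n, k=1)
    keep = scores.top_k_indices(n_edges)
    g = nx.Graph()
    g.add_edges_from(
        (scores.gene_ids[idx_i[m]], scores.gene_ids[idx_j[m]]) for m in keep
    )
    return g


def summarize_network(g: nx.Graph, seed: int = 0) -> NetworkSummary:
    """Topology summary: size, clustering, assortativity, Louvain modules.

    Louvain is randomised; the partition is made reproducible by seeding.
    Metrics undefined for a particular graph (e.g. degree assortativity of
    a regular graph) are reported as None, other fields still computed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot summarise an empty graph")
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    avg_clustering = nx.average_clustering(g)
    try:
        with np.errstate(invalid="ignore"):
            assort = float(nx.degree_assortativity_coefficient(g))
        if not np.isfinite(assort):
            assort = None
    except (ZeroDivisionError, ValueError):
        assort = None
    if assort is None:
        logger.warning("degree assortativity undefined for this graph")
    communities = nx.community.louvain_communities(g, seed=seed)
    modularity = float(nx.community.modularity(g, communities))
    hubs = sorted(g.nodes, key=lambda v: (-g.degree(v), v))[:100]
    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        avg_degree=2.0 * n_edges / n_nodes,
        avg_clustering=float(avg_clustering),
        degree_assortativity=assort,
        n_communities=len(communities),
        modularity=modularity,
        top_hubs=list(hubs),
        seed=seed,
    )


def hub_overlap(
    summary_low: NetworkSummary, summary_ref: NetworkSummary, top_n: int = 100
) -> float:
    """Fraction of the low-quality network's top hubs found among the
    reference network's top hubs.

    If either network has fewer than ``top_n`` hub entries, the overlap is
    computed over the shorter list (with a warning) rather than failing.
    """
    avail = min(top_n, len(summary_low.top_hubs), len(summary_ref.top_hubs))
    if avail < top_n:
        logger.warning(
            "hub_overlap: only %d hubs available, requested top %d", avail, top_n
        )
    if avail == 0:
        return 0.0
    low = set(summary_low.top_hubs[:avail])
    ref = set(summary_ref.top_hubs[:avail])
    return len(low & ref) / avail


def write_edge_list(path: str | Path, g: nx.Graph) -> None:
    """Tab-separated edge list, one ``gene_a<TAB>gene_b`` row per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def write_graphml(path: str | Path, g: nx.Graph) -> None:
    nx.write_graphml(g, path)
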