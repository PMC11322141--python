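"""Topological characterization of co-occurrence networks.

Summarizes each undirected simple network by node/edge counts, average
degree (2E/N), graph density (2E/(N(N-1))) and the fraction of negative
edges, and exposes unnormalized shortest-path betweenness centrality (the
quantity used to size nodes in network drawings).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .abundance import ConfigurationError


@dataclass(frozen=True)
class TopologySummary:
    """One row of a network topology table."""

    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    negative_fraction: float

    def formatted(self) -> dict:
        """Rounded presentation: 3 decimals for degree/density, percent with
        2 decimals for the negative-edge share."""
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "average_degree": round(self.average_degree, 3),
            "density": round(self.density, 3),
            "negative_pct": f"{self.negative_fraction * 100:.2f}%",
        }


def topology_summary(g: nx.Graph) -> TopologySummary:
    """Compute the summary row for an undirected simple graph (N >= 2)."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ConfigurationError("density undefined for graphs with fewer than 2 nodes")
    negative = sum(1 for _, _, d in g.edges(data=True) if d.get("sign") == "negative")
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        density=2.0 * e / (n * (n - 1)),
        negative_fraction=negative / e if e else 0.0,
    )


def summary_from_counts(n_nodes: int, n_edges: int) -> TopologySummary:
    """Summary of any simple graph with the given node and edge counts
    (average degree and density depend only on N and E)."""
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=0)
    return topology_summary(g)


def betweenness(g: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness on the unweighted graph
    (endpoints excluded; each unordered pair counted once)."""
    return nx.betweenness_centrality(g, normalized=False)


def topology_table(networks: dict[str, nx.Graph]) -> pd.DataFrame:
    """One formatted summary row per labelled network."""
    rows = []
    for label, g in networks.items():
        row = {"label": label}
        row.update(topology_summary(g).formatted())
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", "nodes", "edges", "average_degree", "density", "negative_pct"])
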