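"""Topology of evolved PII networks: centralities and component structure.

The evolved networks are compared qualitatively with present-day
protein-protein interaction networks through three per-node centralities —
degree, shortest-path betweenness and closeness — plus the fraction of nodes
in the giant component.  Self-loops never lie on a geodesic, so they are
excluded from the path-based metrics, but they do count (once) toward a
node's degree, matching the aggregation-cost convention.

Betweenness is Freeman's normalized form (divisor (n-1)(n-2)/2 for
undirected graphs, geodesic-count splitting).  Closeness uses the
Wasserman-Faust component-size scaling ((n_c - 1)/(n - 1) times the
within-component closeness), which degrades gracefully on the fragmented
early networks; an isolated node scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import PIINetwork


@dataclass
class TopologyProfile:
    """Per-node centralities plus binned distributions for one snapshot."""

    per_node: pd.DataFrame  # node_id, role, degree, betweenness, closeness
    degree_pmf: dict[int, float]
    betweenness_hist: tuple[np.ndarray, np.ndarray]  # (masses, bin_edges)
    closeness_hist: tuple[np.ndarray, np.ndarray]
    giant_component_fraction: float

    def write_tsv(self, per_node_path, distributions_path) -> None:
        self.per_node.to_csv(per_node_path, sep="\t", index=False)
        rows = []
        for k, p in sorted(self.degree_pmf.items()):
            rows.append(("degree", float(k), float(k), p))
        for name, (masses, edges) in (
            ("betweenness", self.betweenness_hist),
            ("closeness", self.closeness_hist),
        ):
            for lo, hi, m in zip(edges[:-1], edges[1:], masses):
                rows.append((name, float(lo), float(hi), float(m)))
        pd.DataFrame(
            rows, columns=["metric", "bin_low", "bin_high", "mass"]
        ).to_csv(distributions_path, sep="\t", index=False)


def _simple_graph(network: PIINetwork) -> nx.Graph:
    g = network.to_networkx(include_self_loops=False)
    return g


def degree_distribution(network: PIINetwork) -> dict[int, float]:
    """Empirical pmf p(k) of node degree (self-loops count once)."""
    degs = network.degrees()
    n = network.n_nodes
    ks, counts = np.unique(degs, return_counts=True)
    return {int(k): float(c) / n for k, c in zip(ks, counts)}


def betweenness_centrality(network: PIINetwork) -> dict[int, float]:
    """Freeman shortest-path betweenness, normalized by (n-1)(n-2)/2."""
    g = _simple_graph(network)
    return {
        int(node): float(val)
        for node, val in nx.betweenness_centrality(g, normalized=True).items()
    }


def closeness_centrality(network: PIINetwork) -> dict[int, float]:
    """Component-scaled (Wasserman-Faust) closeness; isolated nodes score 0."""
    g = _simple_graph(network)
    return {
        int(node): float(val)
        for node, val in nx.closeness_centrality(g, wf_improved=True).items()
    }


def giant_component(network: PIINetwork) -> tuple[frozenset[int], float]:
    """Largest connected component and its node fraction.

    Self-loops do not connect anything.  Ties are broken in favor of the
    component containing the lowest node id.
    """
    g = _simple_graph(network)
    components = [frozenset(c) for c in nx.connected_components(g)]
    best = max(components, key=lambda c: (len(c), -min(c)))
    return best, len(best) / network.n_nodes


def topology_profile(network: PIINetwork, n_bins: int = 10) -> TopologyProfile:
    """Assemble all per-node centralities and binned distributions."""
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    degs = network.degrees()
    bet = betweenness_centrality(network)
    clo = closeness_centrality(network)
    per_node = pd.DataFrame(
        {
            "node_id": [p.id for p in network.polymers],
            "role": [p.role.value for p in network.polymers],
            "degree": degs,
            "betweenness": [bet[p.id] for p in network.polymers],
            "closeness": [clo[p.id] for p in network.polymers],
        }
    )
    _, frac = giant_component(network)

    def hist(values):
        counts, edges = np.histogram(list(values), bins=n_bins, range=(0.0, 1.0))
        masses = counts / counts.sum() if counts.sum() else counts.astype(float)
        return masses, edges

    return TopologyProfile(
        per_node=per_node,
        degree_pmf=degree_distribution(network),
        betweenness_hist=hist(bet.values()),
        closeness_hist=hist(clo.values()),
        giant_component_fraction=frac,
    )
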