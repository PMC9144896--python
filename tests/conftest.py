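"""Shared fixtures: hand-built small networks and brute-force oracles.

The oracles here deliberately avoid the library's own code paths (and
networkx): subgraph counts by exhaustive triple/pair enumeration, geodesics
by depth-first path enumeration, distances by Floyd-Warshall.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from piinet import PIINetwork, PolymerSpec, Role


def build_network(roles, lengths, links, copies=None):
    """Construct a PIINetwork from role letters, lengths and a link list.

    ``roles`` is a string over {'F' plain functional, 'R' ribosome-like,
    'P' polymerase-like, 'I' informational}; ``links`` is an iterable of
    (a, b) pairs (a == b makes a self-loop).
    """
    role_map = {
        "F": Role.FUNCTIONAL,
        "R": Role.PROTEIN_COPIER,
        "P": Role.XNA_COPIER,
        "I": Role.INFORMATIONAL,
    }
    n = len(roles)
    copies = copies or [1] * n
    polymers = tuple(
        PolymerSpec(i, role_map[roles[i]], lengths[i], copies[i])
        for i in range(n)
    )
    adj = np.zeros((n, n), dtype=np.uint8)
    for a, b in links:
        adj[a, b] = 1
        adj[b, a] = 1
    return PIINetwork(polymers, adj)


@pytest.fixture
def triangle_net():
    """F(L=12)-R-I(L=12) complete translation triangle plus a spare P."""
    return build_network(
        "FRIP", [12, 8, 12, 6],
        [(0, 1), (1, 2), (0, 2)],
    )


@pytest.fixture
def pair_net():
    """P-I link plus the I self-loop: one complete replication pair."""
    return build_network("RPIF", [10, 6, 10, 7], [(1, 2), (2, 2)])


def random_network(rng, n_extra=4, link_prob=0.3, length_choices=(10, 11)):
    """Small random network with one R, one P and mixed F/I nodes."""
    roles = "RP"
    for _ in range(n_extra):
        roles += rng.choice(["F", "I"])
    n = len(roles)
    lengths = [int(rng.choice(length_choices)) for _ in range(n)]
    links = [
        (a, b)
        for a in range(n)
        for b in range(a, n)
        if rng.random() < link_prob
    ]
    return build_network(roles, lengths, links)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_triangles(net: PIINetwork):
    """Exhaustive scan over all (j, R, mu) triples."""
    adj = net.adjacency
    lengths = net.lengths
    out = []
    for j in net.plain_functional_nodes:
        for r in sorted(net.ribosome_nodes):
            for mu in net.informational_nodes:
                if (
                    adj[j, r]
                    and adj[r, mu]
                    and adj[j, mu]
                    and lengths[j] == lengths[mu]
                ):
                    out.append((j, r, mu))
    return sorted(out)


def brute_pairs(net: PIINetwork):
    adj = net.adjacency
    return sorted(
        (p, mu)
        for p in sorted(net.polymerase_nodes)
        for mu in net.informational_nodes
        if adj[p, mu] and adj[mu, mu]
    )


def _neighbors(net, v):
    return [u for u in range(net.n_nodes) if u != v and net.adjacency[v, u]]


def brute_geodesics(net: PIINetwork, s: int, t: int):
    """(distance, list of shortest paths) by DFS path enumeration; self-loops
    ignored.  Returns (None, []) if unreachable."""
    best: list[list[int]] = []
    best_len = [None]

    def extend(path):
        v = path[-1]
        if v == t:
            d = len(path) - 1
            if best_len[0] is None or d < best_len[0]:
                best_len[0] = d
                best.clear()
            if d == best_len[0]:
                best.append(list(path))
            return
        if best_len[0] is not None and len(path) - 1 >= best_len[0]:
            return
        for u in _neighbors(net, v):
            if u not in path:
                path.append(u)
                extend(path)
                path.pop()

    extend([s])
    return best_len[0], best


def brute_betweenness(net: PIINetwork):
    """Freeman betweenness from explicit geodesic enumeration."""
    n = net.n_nodes
    score = {v: 0.0 for v in range(n)}
    for s, t in itertools.combinations(range(n), 2):
        d, paths = brute_geodesics(net, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2.0
        score = {v: x / norm for v, x in score.items()}
    return score


def brute_distances(net: PIINetwork):
    """All-pairs shortest-path matrix by Floyd-Warshall; inf if disconnected."""
    n = net.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for v in range(n):
        for u in _neighbors(net, v):
            dist[v, u] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_closeness(net: PIINetwork):
    """Wasserman-Faust component-scaled closeness from the distance matrix."""
    n = net.n_nodes
    dist = brute_distances(net)
    out = {}
    for v in range(n):
        reach = np.isfinite(dist[v])
        n_c = int(reach.sum())  # includes v itself
        if n_c <= 1 or n <= 1:
            out[v] = 0.0
            continue
        total = dist[v][reach].sum()
        out[v] = ((n_c - 1) / (n - 1)) * ((n_c - 1) / total)
    return out
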