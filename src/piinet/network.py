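"""Protein-informational interaction (PII) networks.

Nodes are molecular *types* — short functional polymers (peptides, including
ribosome-like protein copiers and polymerase-like xNA copiers) and
informational polymers (xNAs, i.e. DNA or RNA).  A link means some physical
interaction between the two populations; self-loops are meaningful (an xNA
that binds its own kind is a template for replication).  The adjacency is
binary and symmetric, and evolution acts on it one link flip at a time.

Two small subgraphs carry all of the catalytic function:

* protein copier (translation): a triangle ``j–R``, ``R–mu``, ``j–mu`` where
  ``R`` is a ribosome-like node, ``j`` a plain functional node and ``mu`` an
  informational node with the *same chain length* as ``j`` (a one-to-one
  primitive code);
* xNA copier (replication): a pair ``P–mu`` plus the self-loop ``mu–mu``
  where ``P`` is a polymerase-like node.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class Role(str, enum.Enum):
    """What a polymer type does in the network."""

    FUNCTIONAL = "functional"
    INFORMATIONAL = "informational"
    PROTEIN_COPIER = "protein_copier"  # ribosome-like (a protein)
    XNA_COPIER = "xna_copier"          # polymerase-like (a protein)


#: Roles that count as functional (copiers are proteins).
FUNCTIONAL_ROLES = frozenset(
    {Role.FUNCTIONAL, Role.PROTEIN_COPIER, Role.XNA_COPIER}
)


class ParameterError(ValueError):
    """Invalid generation or model parameters."""


class StateError(RuntimeError):
    """An operation inconsistent with the current network state."""


@dataclass(frozen=True)
class PolymerSpec:
    """One molecular type: node id, role, chain length and initial copy number."""

    id: int
    role: Role
    length: int
    initial_copies: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ParameterError(f"length must be >= 1, got {self.length}")
        if self.initial_copies < 1:
            raise ParameterError(
                f"initial_copies must be >= 1, got {self.initial_copies}"
            )

    @property
    def is_functional(self) -> bool:
        return self.role in FUNCTIONAL_ROLES


class Direction(str, enum.Enum):
    ADD = "add"
    REMOVE = "remove"


@dataclass(frozen=True)
class MutationEvent:
    """A single proposed link flip at the unordered pair (node_a, node_b)."""

    node_a: int
    node_b: int
    direction: Direction


@dataclass
class PIINetwork:
    """A PII network: polymer specs plus a symmetric binary adjacency matrix.

    ``adjacency[a, b] == adjacency[b, a]`` always; diagonal entries are
    self-loops.  Copier designations are derived from the polymer roles.
    """

    polymers: tuple[PolymerSpec, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        n = len(self.polymers)
        if self.adjacency.shape != (n, n):
            raise StateError(
                f"adjacency shape {self.adjacency.shape} != ({n}, {n})"
            )
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise StateError("adjacency is not symmetric")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise StateError("adjacency entries must be 0 or 1")
        ids = [p.id for p in self.polymers]
        if ids != list(range(n)):
            raise StateError("polymer ids must be 0..n-1 in order")
        if not self.ribosome_nodes or not self.polymerase_nodes:
            raise StateError("need at least one protein copier and one xNA copier")

    # -- node bookkeeping --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.polymers)

    @property
    def ribosome_nodes(self) -> frozenset[int]:
        return frozenset(
            p.id for p in self.polymers if p.role is Role.PROTEIN_COPIER
        )

    @property
    def polymerase_nodes(self) -> frozenset[int]:
        return frozenset(p.id for p in self.polymers if p.role is Role.XNA_COPIER)

    @property
    def functional_nodes(self) -> tuple[int, ...]:
        return tuple(p.id for p in self.polymers if p.is_functional)

    @property
    def plain_functional_nodes(self) -> tuple[int, ...]:
        """Functional nodes that may serve as translation substrates j."""
        return tuple(p.id for p in self.polymers if p.role is Role.FUNCTIONAL)

    @property
    def informational_nodes(self) -> tuple[int, ...]:
        return tuple(
            p.id for p in self.polymers if p.role is Role.INFORMATIONAL
        )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([p.length for p in self.polymers], dtype=np.int64)

    # -- links and degrees -------------------------------------------------

    def link_count(self) -> int:
        """Total links: off-diagonal unordered pairs plus self-loops."""
        a = self.adjacency
        return int((np.triu(a, 1).sum()) + np.diag(a).sum())

    def node_degree(self, node: int) -> int:
        """Number of links incident to ``node``; a self-loop counts once."""
        if not 0 <= node < self.n_nodes:
            raise KeyError(f"unknown node {node}")
        row = self.adjacency[node]
        return int(row.sum())  # diagonal entry contributes exactly 1

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    # -- mutation ----------------------------------------------------------

    def copy(self) -> "PIINetwork":
        return PIINetwork(self.polymers, self.adjacency.copy())

    # -- conversions -------------------------------------------------------

    def to_networkx(self, include_self_loops: bool = True):
        """Undirected networkx graph with role/length node attributes."""
        import networkx as nx

        g = nx.Graph()
        for p in self.polymers:
            g.add_node(
                p.id,
                role=p.role.value,
                length=p.length,
                initial_copies=p.initial_copies,
            )
        for a, b in zip(*np.nonzero(np.triu(self.adjacency))):
            if a == b and not include_self_loops:
                continue
            g.add_edge(int(a), int(b))
        return g

    # -- serialization -----------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": [p.id for p in self.polymers],
                "role": [p.role.value for p in self.polymers],
                "length": [p.length for p in self.polymers],
                "initial_copies": [p.initial_copies for p in self.polymers],
            }
        )

    def edge_table(self) -> pd.DataFrame:
        rows = np.transpose(np.nonzero(np.triu(self.adjacency)))
        return pd.DataFrame(rows, columns=["node_a", "node_b"], dtype=np.int64)

    def write_tsv(self, nodes_path, edges_path) -> None:
        self.node_table().to_csv(nodes_path, sep="\t", index=False)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, nodes_path, edges_path) -> "PIINetwork":
        nodes = pd.read_csv(nodes_path, sep="\t")
        edges = pd.read_csv(edges_path, sep="\t")
        polymers = tuple(
            PolymerSpec(
                id=int(r.node_id),
                role=Role(r.role),
                length=int(r.length),
                initial_copies=int(r.initial_copies),
            )
            for r in nodes.itertuples()
        )
        n = len(polymers)
        adj = np.zeros((n, n), dtype=np.uint8)
        for r in edges.itertuples():
            adj[int(r.node_a), int(r.node_b)] = 1
            adj[int(r.node_b), int(r.node_a)] = 1
        return cls(polymers, adj)

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


# ---------------------------------------------------------------------------
# pair enumeration helpers
# ---------------------------------------------------------------------------

def unordered_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered node pairs including self-pairs: n*(n+1)/2 of them."""
    return [(a, b) for a in range(n) for b in range(a, n)]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_initial_network(
    n_functional: int,
    n_informational: int,
    link_prob: float,
    length_range: tuple[int, int] = (5, 25),
    n_ribosome: int = 1,
    n_polymerase: int = 1,
    initial_copies: int = 1,
    rng_seed: int | None = None,
) -> PIINetwork:
    """Random PII network: each unordered pair (self-pairs included) linked
    independently with probability ``link_prob``; lengths uniform on the
    inclusive ``length_range``; any complete copier subgraph is then broken
    by removing uniformly chosen links until none remain, so evolution starts
    with zero catalytic machines.
    """
    if n_functional < 1 or n_informational < 1:
        raise ParameterError("need at least one functional and one informational type")
    if n_ribosome < 1 or n_polymerase < 1:
        raise ParameterError("need at least one ribosome-like and one polymerase-like node")
    if n_ribosome + n_polymerase > n_functional:
        raise ParameterError("copier count exceeds functional type count")
    if not 0.0 <= link_prob <= 1.0:
        raise ParameterError(f"link_prob must be in [0, 1], got {link_prob}")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1 or hi < lo:
        raise ParameterError(f"invalid length_range {length_range!r}")

    rng = np.random.default_rng(rng_seed)
    n = n_functional + n_informational

    roles = (
        [Role.PROTEIN_COPIER] * n_ribosome
        + [Role.XNA_COPIER] * n_polymerase
        + [Role.FUNCTIONAL] * (n_functional - n_ribosome - n_polymerase)
        + [Role.INFORMATIONAL] * n_informational
    )
    lengths = rng.integers(lo, hi + 1, size=n)
    polymers = tuple(
        PolymerSpec(id=i, role=roles[i], length=int(lengths[i]),
                    initial_copies=initial_copies)
        for i in range(n)
    )

    upper = np.triu(rng.random((n, n)) < link_prob)
    adj = (upper | upper.T).astype(np.uint8)
    net = PIINetwork(polymers, adj)

    # Break every complete copier subgraph: drop one uniformly chosen link
    # from a uniformly chosen complete subgraph, repeat until none remain.
    while True:
        _, triangles = count_protein_copier_subgraphs(net)
        _, pairs = count_xna_copier_subgraphs(net)
        link_sets = [((j, r), (r, mu), (j, mu)) for j, r, mu in triangles]
        link_sets += [((p, mu), (mu, mu)) for p, mu in pairs]
        if not link_sets:
            break
        links = link_sets[rng.integers(len(link_sets))]
        a, b = links[rng.integers(len(links))]
        net.adjacency[a, b] = 0
        net.adjacency[b, a] = 0
    return net


# ---------------------------------------------------------------------------
# mutation proposal / application
# ---------------------------------------------------------------------------

def propose_mutation(network: PIINetwork, rng) -> MutationEvent:
    """Uniformly choose an unordered pair (self-pairs included) and return the
    flip implied by the current state.  The network is not modified.

    ``rng`` may be a ``numpy.random.Generator`` or ``random.Random``.
    """
    n = network.n_nodes
    n_pairs = n * (n + 1) // 2
    if hasattr(rng, "integers"):
        idx = int(rng.integers(n_pairs))
    else:
        idx = rng.randrange(n_pairs)
    a, b = _pair_from_index(idx, n)
    direction = (
        Direction.REMOVE if network.adjacency[a, b] else Direction.ADD
    )
    return MutationEvent(a, b, direction)


def _pair_from_index(idx: int, n: int) -> tuple[int, int]:
    # row a holds n - a pairs: (a, a) .. (a, n-1)
    a = 0
    remaining = idx
    while remaining >= n - a:
        remaining -= n - a
        a += 1
    return a, a + remaining


def apply_mutation(network: PIINetwork, event: MutationEvent) -> PIINetwork:
    """Return a new network with the link at (node_a, node_b) flipped."""
    a, b = event.node_a, event.node_b
    current = int(network.adjacency[a, b])
    if event.direction is Direction.ADD and current:
        raise StateError(f"cannot add link ({a}, {b}): already present")
    if event.direction is Direction.REMOVE and not current:
        raise StateError(f"cannot remove link ({a}, {b}): absent")
    out = network.copy()
    out.adjacency[a, b] = 1 - current
    out.adjacency[b, a] = 1 - current
    return out


# ---------------------------------------------------------------------------
# copier subgraph detection
# ---------------------------------------------------------------------------

def count_protein_copier_subgraphs(
    network: PIINetwork,
) -> tuple[int, list[tuple[int, int, int]]]:
    """Complete translation triangles (j, R, mu).

    j is a plain functional node, R a ribosome-like node and mu informational;
    all three links j-R, R-mu, j-mu must be present and the chain lengths of j
    and mu must match (primitive one-to-one code).
    """
    adj = network.adjacency
    lengths = network.lengths
    triples = []
    for r in sorted(network.ribosome_nodes):
        for j in network.plain_functional_nodes:
            if not adj[j, r]:
                continue
            lj = lengths[j]
            for mu in network.informational_nodes:
                if adj[r, mu] and adj[j, mu] and lengths[mu] == lj:
                    triples.append((j, r, mu))
    return len(triples), triples


def count_xna_copier_subgraphs(
    network: PIINetwork,
) -> tuple[int, list[tuple[int, int]]]:
    """Complete replication pairs (P, mu): link P-mu plus self-loop mu-mu."""
    adj = network.adjacency
    pairs = [
        (p, mu)
        for p in sorted(network.polymerase_nodes)
        for mu in network.informational_nodes
        if adj[p, mu] and adj[mu, mu]
    ]
    return len(pairs), pairs
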