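"""Protocell growth rates.

A protocell grows by elongating the polymer chains inside it and splits when
its volume doubles.  With no catalysis each chain of length L elongates at
k_X / L (constant time per monomer), so the volume grows linearly and the
splitting rate is the reference growth rate

    r0 = (v_F k_F N_F + v_I k_I N_I) / V0,

where V0 = sum_j n_j0 v_F L_j + sum_mu m_mu0 v_I L_mu is the volume right
after a split.  Complete copier subgraphs add autocatalytic elongation terms
(weighted by per-copier effectiveness alpha, beta).  To first order in the
effectiveness, each subgraph boosts the splitting rate by its catalytic
volume production averaged over one unperturbed division cycle:

    delta_r_R = (v_F / V0) * sum_triangles  L_j  * alpha_R * <n_j n_R m_mu>
    delta_r_C = (v_I / V0) * sum_pairs      L_mu * beta_P  * <n_P m_mu^2>

where <.> is the time average along the catalysis-free trajectory
n_i(t) = n_i0 + (k_X / L_i) t over [0, T0], T0 = V0 / (v_F k_F N_F +
v_I k_I N_I).  Copy numbers roughly double within a cycle, so this cycle
average — the exact first-order term — is substantially larger than the
same product frozen at the initial copy numbers.

The exact splitting time of the full nonlinear system is available from a
numeric ODE integration and serves as the reference oracle for those
perturbative boosts.  Finally, promiscuous binding carries an aggregation
cost g(k) = delta * d(k) for every node whose link count d(k) reaches the
threshold D, subtracted from the total rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    PIINetwork,
    ParameterError,
    count_protein_copier_subgraphs,
    count_xna_copier_subgraphs,
)

#: r_total is floored at this fraction of r0 so log-fitness stays defined;
#: a mutation that drives the rate to the floor is effectively lethal.
RATE_FLOOR_FRACTION = 1e-12


class DegenerateStateError(ValueError):
    """A protocell state with no volume (no polymers)."""


@dataclass(frozen=True)
class AggregationParams:
    """Aggregation cost: nodes with degree >= threshold_D pay delta * degree."""

    threshold_D: int = 5
    delta: float = 0.005

    def __post_init__(self) -> None:
        if self.threshold_D < 1:
            raise ParameterError(f"threshold_D must be >= 1, got {self.threshold_D}")
        if self.delta < 0:
            raise ParameterError(f"delta must be >= 0, got {self.delta}")

    def cost(self, degree: int) -> float:
        """g(k): zero below threshold, delta * d(k) at or above it."""
        return 0.0 if degree < self.threshold_D else self.delta * degree


@dataclass
class ProtocellState:
    """Copy numbers, kinetic constants and copier effectiveness for one cell.

    ``copies`` is indexed by node id (n_j0 for functional types, m_mu0 for
    informational types).  ``alpha`` maps each ribosome-like node to its
    translation effectiveness in [0, 1]; ``beta`` likewise for
    polymerase-like nodes.
    """

    copies: np.ndarray
    k_F: float = 1.0
    k_I: float = 1.0
    v_F: float = 1.0
    v_I: float = 1.0
    alpha: dict[int, float] = field(default_factory=dict)
    beta: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if (self.copies < 1).any():
            raise ParameterError("all copy numbers must be >= 1")
        for name in ("k_F", "k_I", "v_F", "v_I"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for label, table in (("alpha", self.alpha), ("beta", self.beta)):
            for node, val in table.items():
                if not 0.0 <= val <= 1.0:
                    raise ParameterError(
                        f"{label}[{node}] must be in [0, 1], got {val}"
                    )

    @classmethod
    def for_network(
        cls,
        network: PIINetwork,
        k_F: float = 1.0,
        k_I: float = 1.0,
        v_F: float = 1.0,
        v_I: float = 1.0,
        alpha: dict[int, float] | None = None,
        beta: dict[int, float] | None = None,
        rng_seed: int | None = None,
    ) -> "ProtocellState":
        """State matching a network's initial copy numbers.

        Unless given explicitly, each copier node draws its effectiveness
        once, uniformly from [0, 1] (most primordial copy machines are
        error-prone; a lucky few are accurate).
        """
        rng = np.random.default_rng(rng_seed)
        if alpha is None:
            alpha = {r: float(rng.random()) for r in sorted(network.ribosome_nodes)}
        if beta is None:
            beta = {p: float(rng.random()) for p in sorted(network.polymerase_nodes)}
        copies = np.array([p.initial_copies for p in network.polymers])
        return cls(copies=copies, k_F=k_F, k_I=k_I, v_F=v_F, v_I=v_I,
                   alpha=alpha, beta=beta)


@dataclass(frozen=True)
class GrowthRates:
    """Decomposition of a protocell's net growth rate."""

    r0: float
    delta_r_R: float
    delta_r_C: float
    aggregation_penalty: float
    r_total: float


# ---------------------------------------------------------------------------
# reference quantities
# ---------------------------------------------------------------------------

def _volume_weights(state: ProtocellState, network: PIINetwork) -> np.ndarray:
    """Per-node volume of one mature chain: v_X * L."""
    w = np.empty(network.n_nodes)
    lengths = network.lengths
    for p in network.polymers:
        vx = state.v_F if p.is_functional else state.v_I
        w[p.id] = vx * lengths[p.id]
    return w


def reference_volume(state: ProtocellState, network: PIINetwork) -> float:
    """V0: protocell volume right after a split, at the initial copy numbers."""
    if network.n_nodes == 0:
        raise DegenerateStateError("no polymer types: V0 undefined")
    return float(state.copies @ _volume_weights(state, network))


def reference_growth_rate(state: ProtocellState, network: PIINetwork) -> float:
    """r0 = (v_F k_F N_F + v_I k_I N_I) / V0 — splitting rate with no catalysis."""
    v0 = reference_volume(state, network)
    if v0 <= 0:
        raise DegenerateStateError("V0 must be positive")
    n_f = len(network.functional_nodes)
    n_i = len(network.informational_nodes)
    return (state.v_F * state.k_F * n_f + state.v_I * state.k_I * n_i) / v0


# ---------------------------------------------------------------------------
# elongation kinetics
# ---------------------------------------------------------------------------

def elongation_derivatives(
    state: ProtocellState,
    network: PIINetwork,
    copies_now: np.ndarray,
) -> np.ndarray:
    """d(copies)/dt for every polymer type at the given instantaneous copies.

    Baseline elongation contributes k_X / L to every type.  Each complete
    translation triangle (j, R, mu) adds alpha_R * n_j n_R m_mu to dn_j/dt;
    each complete replication pair (P, mu) adds beta_P * n_P m_mu^2 to
    dm_mu/dt.  Catalysis only acts through *complete* subgraphs.
    """
    copies_now = np.asarray(copies_now, dtype=float)
    lengths = network.lengths.astype(float)
    deriv = np.empty(network.n_nodes)
    for p in network.polymers:
        kx = state.k_F if p.is_functional else state.k_I
        deriv[p.id] = kx / lengths[p.id]

    _, triangles = count_protein_copier_subgraphs(network)
    for j, r, mu in triangles:
        deriv[j] += state.alpha[r] * copies_now[j] * copies_now[r] * copies_now[mu]
    _, pairs = count_xna_copier_subgraphs(network)
    for p_node, mu in pairs:
        deriv[mu] += state.beta[p_node] * copies_now[p_node] * copies_now[mu] ** 2
    return deriv


def splitting_time_numeric(
    state: ProtocellState,
    network: PIINetwork,
    tol: float = 1e-10,
    max_horizon_factor: float = 20.0,
) -> tuple[float, float]:
    """Integrate the coupled elongation ODEs until the volume doubles.

    Returns (T_s, 1/T_s).  The doubling time is located by the integrator's
    event root-finding on total volume = 2 V0.  This is the exact-dynamics
    oracle against which the perturbative copier boosts are validated.
    """
    v0 = reference_volume(state, network)
    weights = _volume_weights(state, network)
    baseline_rate = reference_growth_rate(state, network)
    horizon = max_horizon_factor / baseline_rate

    def rhs(_t, y):
        return elongation_derivatives(state, network, y)

    def doubled(_t, y):
        return float(y @ weights) - 2.0 * v0

    doubled.terminal = True
    doubled.direction = 1

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        state.copies.astype(float),
        events=doubled,
        rtol=tol,
        atol=tol * float(state.copies.max()),
        dense_output=False,
        method="RK45",
    )
    if not sol.t_events[0].size:
        raise RuntimeError(
            f"volume did not double within horizon {horizon:g}; "
            "check rates and effectiveness values"
        )
    t_s = float(sol.t_events[0][0])
    return t_s, 1.0 / t_s


# ---------------------------------------------------------------------------
# perturbative copier boosts
# ---------------------------------------------------------------------------

def _cycle_average_product(factors, t0: float) -> float:
    """Average over [0, t0] of a product of linear functions (c0 + slope*t).

    The product of up to three linears is a cubic; integrate it exactly.
    """
    poly = np.array([1.0])
    for c0, slope in factors:
        poly = np.polymul(poly, [slope, c0])
    return float(np.polyval(np.polyint(poly), t0)) / t0


def candidate_boost_weights(
    state: ProtocellState, network: PIINetwork
) -> tuple[dict[tuple[int, int, int], float], dict[tuple[int, int], float]]:
    """First-order boost weight of every *possible* copier subgraph.

    Keys are (j, R, mu) triangles (length-matched only) and (P, mu) pairs;
    the weight is the growth-rate gain the subgraph would contribute if all
    of its links were present.  Weights depend only on the polymer specs and
    kinetics, not on the current adjacency, so they can be computed once per
    protocell composition and reused across an entire trajectory.
    """
    v0 = reference_volume(state, network)
    n_f = len(network.functional_nodes)
    n_i = len(network.informational_nodes)
    t0 = v0 / (state.v_F * state.k_F * n_f + state.v_I * state.k_I * n_i)
    lengths = network.lengths.astype(float)
    c = state.copies.astype(float)

    def lin(node: int) -> tuple[float, float]:
        functional = network.polymers[node].is_functional
        k = state.k_F if functional else state.k_I
        return c[node], k / lengths[node]

    tri_weights: dict[tuple[int, int, int], float] = {}
    for r in sorted(network.ribosome_nodes):
        for j in network.plain_functional_nodes:
            for mu in network.informational_nodes:
                if lengths[j] != lengths[mu]:
                    continue
                avg = _cycle_average_product([lin(j), lin(r), lin(mu)], t0)
                tri_weights[(j, r, mu)] = (
                    state.v_F * lengths[j] * state.alpha[r] * avg / v0
                )
    pair_weights: dict[tuple[int, int], float] = {}
    for p in sorted(network.polymerase_nodes):
        for mu in network.informational_nodes:
            avg = _cycle_average_product([lin(p), lin(mu), lin(mu)], t0)
            pair_weights[(p, mu)] = (
                state.v_I * lengths[mu] * state.beta[p] * avg / v0
            )
    return tri_weights, pair_weights


def copier_rate_boost(
    state: ProtocellState, network: PIINetwork
) -> tuple[float, float]:
    """First-order growth-rate boosts (delta_r_R, delta_r_C).

    Sums the cycle-averaged catalytic weight of every *complete* copier
    subgraph; both are zero when no complete subgraph exists.
    """
    tri_weights, pair_weights = candidate_boost_weights(state, network)
    _, triangles = count_protein_copier_subgraphs(network)
    _, pairs = count_xna_copier_subgraphs(network)
    d_r = sum(tri_weights[t] for t in triangles)
    d_c = sum(pair_weights[p] for p in pairs)
    return d_r, d_c


# ---------------------------------------------------------------------------
# aggregation and the total rate
# ---------------------------------------------------------------------------

def aggregation_cost(network: PIINetwork, params: AggregationParams) -> float:
    """Sum of g(k) over all nodes (self-loops count once toward degree)."""
    return float(sum(params.cost(int(d)) for d in network.degrees()))


def total_growth_rate(
    state: ProtocellState,
    network: PIINetwork,
    params: AggregationParams,
) -> GrowthRates:
    """Net protocell growth rate r = r0 + delta_r_R + delta_r_C - sum g(k).

    The net rate is floored at RATE_FLOOR_FRACTION * r0 so that log-fitness
    is always defined; a protocell at the floor is effectively dead.
    """
    r0 = reference_growth_rate(state, network)
    d_r, d_c = copier_rate_boost(state, network)
    penalty = aggregation_cost(network, params)
    raw = r0 + d_r + d_c - penalty
    r_total = max(raw, RATE_FLOOR_FRACTION * r0)
    return GrowthRates(
        r0=r0,
        delta_r_R=d_r,
        delta_r_C=d_c,
        aggregation_penalty=penalty,
        r_total=r_total,
    )
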