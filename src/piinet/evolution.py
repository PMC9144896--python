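"""Mutation-selection-drift dynamics over a population of protocells.

The population never appears explicitly: in the strong-selection /
weak-mutation regime one mutation is in play at a time.  Each step proposes
a single link flip, evaluates the mutant protocell's growth rate, converts
the log-rate difference s into a fixation probability via Kimura's formula
(or 1/(2N) for neutral flips), and draws whether the mutant sweeps the
population.  If it does, the mutant network becomes the new wild type;
otherwise the flip is discarded.

The mutant rate is evaluated incrementally: a single flip can only create or
destroy copier subgraphs that contain the flipped pair, and only changes the
degrees of its two endpoints, so each proposal costs O(number of candidate
third nodes) rather than a full network scan.  The cached wild-type rate
decomposition is recomputed from scratch on every fixation (fixations are
rare) and cross-checked against a full recomputation every
``resync_interval`` steps.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth as _growth
from .network import (
    Direction,
    MutationEvent,
    PIINetwork,
    ParameterError,
    Role,
    StateError,
    count_protein_copier_subgraphs,
    count_xna_copier_subgraphs,
)
from .growth import AggregationParams, ProtocellState, total_growth_rate


# ---------------------------------------------------------------------------
# selection and fixation
# ---------------------------------------------------------------------------

def selection_coefficient(r_mut: float, r_wt: float) -> float:
    """s = log r_mut - log r_wt (fitness is the log of the growth rate)."""
    if r_mut <= 0 or r_wt <= 0:
        raise ValueError("growth rates must be positive")
    return math.log(r_mut) - math.log(r_wt)


def fixation_probability(
    s: float, pop_size: int, neutral_eps: float = 1e-12
) -> float:
    """Kimura fixation probability of a single mutant in N protocells.

    Neutral flips (|s| < neutral_eps) fix with probability 1/(2N); otherwise
    (1 - e^{-2s}) / (1 - e^{-4Ns}), evaluated with overflow-safe asymptotics
    for large |4Ns|.  Applied for deleterious s as well, where it yields a
    tiny but nonzero probability, per Kimura's diffusion result.
    """
    if pop_size < 2:
        raise ParameterError(f"pop_size must be >= 2, got {pop_size}")
    if abs(s) < neutral_eps:
        return 1.0 / (2.0 * pop_size)
    x = 4.0 * pop_size * s
    if abs(x) <= 700.0:
        return -math.expm1(-2.0 * s) / -math.expm1(-x)
    if s > 0:
        # denominator is 1 to machine precision
        return -math.expm1(-2.0 * s)
    # s < 0 with huge 4N|s|: mu = (e^{-2s} - 1) / (e^{-4Ns} - 1)
    #                           ~= exp(4Ns + log(e^{-2s} - 1))
    log_num = -2.0 * s if -2.0 * s > 700.0 else math.log(math.expm1(-2.0 * s))
    log_mu = x + log_num
    return math.exp(log_mu) if log_mu > -745.0 else 0.0


def classify_mutation(s: float, neutral_eps: float = 1e-12) -> str:
    """'beneficial' (s > eps), 'deleterious' (s < -eps) or 'neutral'."""
    if s > neutral_eps:
        return "beneficial"
    if s < -neutral_eps:
        return "deleterious"
    return "neutral"


# ---------------------------------------------------------------------------
# parameters and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionParams:
    """Settings for one evolution trajectory.

    ``pop_size`` is the protocell population entering Kimura's formula;
    ``n_mutations`` the number of proposed flips; ``neutral_eps`` the |s|
    threshold below which a flip counts as neutral (flips that change no
    subgraph and no aggregation term give bit-identical rates, so this only
    guards float noise).  ``fixation_override`` forces the fixation
    probability to a constant (testing hook).  ``resync_interval`` sets how
    often the incremental rate cache is checked against a full recomputation.
    """

    pop_size: int = 100_000
    n_mutations: int = 1_000_000
    neutral_eps: float = 1e-12
    rng_seed: int = 0
    aggregation: AggregationParams = field(default_factory=AggregationParams)
    fixation_override: float | None = None
    resync_interval: int = 10_000
    keep_log: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ParameterError(f"pop_size must be >= 2, got {self.pop_size}")
        if self.n_mutations < 1:
            raise ParameterError("n_mutations must be >= 1")
        if self.neutral_eps <= 0:
            raise ParameterError("neutral_eps must be > 0")


@dataclass
class TrajectoryRecord:
    """Full per-mutation log of one trajectory plus summary tallies."""

    seed: int
    initial_network: PIINetwork
    final_network: PIINetwork
    n_mutations: int
    n_beneficial: int
    n_neutral: int
    n_deleterious: int
    n_fixed: int
    n_fixed_beneficial: int
    n_fixed_neutral: int
    n_fixed_deleterious: int
    n_fixed_adds: int
    n_fixed_adds_copier: int
    initial_link_count: int
    final_link_count: int
    final_r_wt: float
    # per-step columns; None when keep_log=False
    log: dict[str, np.ndarray] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        if self.log is None:
            raise StateError("trajectory was run with keep_log=False")
        return pd.DataFrame(self.log)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_LOG_COLUMNS = (
    ("step", np.int64),
    ("node_a", np.int16),
    ("node_b", np.int16),
    ("action", object),  # 'add' / 'remove'
    ("s", np.float64),
    ("fix_prob", np.float64),
    ("fixed", np.bool_),
    ("r_wt", np.float64),
    ("r_mut", np.float64),
    ("n_links", np.int32),
    ("n_tri", np.int32),
    ("n_pairs", np.int32),
)


# ---------------------------------------------------------------------------
# the trajectory engine
# ---------------------------------------------------------------------------

def _rate_components(network, state, params):
    """(r0, boost_R, boost_C, agg, n_tri, n_pairs) computed from scratch."""
    r0 = _growth.reference_growth_rate(state, network)
    b_r, b_c = _growth.copier_rate_boost(state, network)
    agg = _growth.aggregation_cost(network, params.aggregation)
    n_tri, _ = count_protein_copier_subgraphs(network)
    n_pair, _ = count_xna_copier_subgraphs(network)
    return r0, b_r, b_c, agg, n_tri, n_pair


def run_trajectory(
    network: PIINetwork,
    state: ProtocellState,
    params: EvolutionParams,
    allow_initial_subgraphs: bool = False,
) -> TrajectoryRecord:
    """Run the propose -> evaluate -> fix-or-revert loop for n_mutations steps.

    The starting network is required to contain no complete copier subgraph
    (evolution must *discover* the machines) unless explicitly overridden.
    Bit-identical output is guaranteed for a fixed ``params.rng_seed``.
    """
    n_tri0, _ = count_protein_copier_subgraphs(network)
    n_pair0, _ = count_xna_copier_subgraphs(network)
    if not allow_initial_subgraphs and (n_tri0 or n_pair0):
        raise StateError(
            "initial network already contains complete copier subgraphs; "
            "pass allow_initial_subgraphs=True to accept it"
        )

    n = network.n_nodes
    net = network.copy()
    adj = [bytearray(bytes(net.adjacency[i])) for i in range(n)]
    deg = [int(d) for d in net.degrees()]
    lengths = [int(x) for x in net.lengths]

    roles = [p.role for p in net.polymers]
    ribosomes = sorted(net.ribosome_nodes)
    polymerases = sorted(net.polymerase_nodes)
    plain_func = list(net.plain_functional_nodes)
    info_nodes = list(net.informational_nodes)
    is_copier = [r in (Role.PROTEIN_COPIER, Role.XNA_COPIER) for r in roles]

    # first-order boost weight of every possible subgraph, fixed for the
    # whole trajectory (copy numbers reset to n_j0, m_mu0 each generation)
    tri_weights, pair_weights = _growth.candidate_boost_weights(state, net)

    def tri_w(j, r, mu):
        return tri_weights[(j, r, mu)]

    def pair_w(p, mu):
        return pair_weights[(p, mu)]

    # informational nodes grouped by length, for the j-R and R-mu flip cases
    info_by_length: dict[int, list[int]] = {}
    for mu in info_nodes:
        info_by_length.setdefault(lengths[mu], []).append(mu)
    func_by_length: dict[int, list[int]] = {}
    for j in plain_func:
        func_by_length.setdefault(lengths[j], []).append(j)

    r0, b_r, b_c, agg, n_tri, n_pair = _rate_components(net, state, params)
    floor = _growth.RATE_FLOOR_FRACTION * r0
    r_wt = max(r0 + b_r + b_c - agg, floor)
    log_r_wt = math.log(r_wt)

    d_thresh = params.aggregation.threshold_D
    delta = params.aggregation.delta

    def g(d):
        return 0.0 if d < d_thresh else delta * d

    rng = random.Random(params.rng_seed)
    n_pairs_total = n * (n + 1) // 2
    pair_of = [
        (a, b) for a in range(n) for b in range(a, n)
    ]

    if params.keep_log:
        log = {
            name: np.empty(params.n_mutations, dtype=dt)
            for name, dt in _LOG_COLUMNS
        }
    else:
        log = None

    n_links = net.link_count()
    initial_links = n_links
    tallies = {"beneficial": 0, "neutral": 0, "deleterious": 0}
    fixed_tallies = {"beneficial": 0, "neutral": 0, "deleterious": 0}
    n_fixed = 0
    n_fixed_adds = 0
    n_fixed_adds_copier = 0

    ribo_set = set(ribosomes)
    poly_set = set(polymerases)
    info_set = set(info_nodes)
    plain_set = set(plain_func)

    def flip_deltas(a, b):
        """Signed-magnitude subgraph/aggregation changes for flipping (a, b).

        Returns (w_r, w_c, d_sub, dagg) where w_r/w_c are the *positive*
        total weights of translation/replication subgraphs whose existence
        toggles with this link, d_sub the corresponding (tri, pair) counts,
        and dagg the signed aggregation-cost change.
        """
        w_r = 0.0
        w_c = 0.0
        d_tri = 0
        d_pair = 0
        if a == b:
            if a in info_set:
                row = adj[a]
                for p in polymerases:
                    if row[p]:
                        w_c += pair_w(p, a)
                        d_pair += 1
        else:
            a_plain = a in plain_set
            b_plain = b in plain_set
            a_info = a in info_set
            b_info = b in info_set
            if (a_plain and b_info) or (b_plain and a_info):
                j, mu = (a, b) if a_plain else (b, a)
                if lengths[j] == lengths[mu]:
                    row_j = adj[j]
                    row_mu = adj[mu]
                    for r in ribosomes:
                        if row_j[r] and row_mu[r]:
                            w_r += tri_w(j, r, mu)
                            d_tri += 1
            elif a in ribo_set or b in ribo_set:
                r, other = (a, b) if a in ribo_set else (b, a)
                row_r = adj[r]
                row_o = adj[other]
                if other in plain_set:
                    for mu in info_by_length.get(lengths[other], ()):
                        if row_r[mu] and row_o[mu]:
                            w_r += tri_w(other, r, mu)
                            d_tri += 1
                elif other in info_set:
                    for j in func_by_length.get(lengths[other], ()):
                        if row_r[j] and row_o[j]:
                            w_r += tri_w(j, r, other)
                            d_tri += 1
            if (a in poly_set and b_info) or (b in poly_set and a_info):
                p, mu = (a, b) if a in poly_set else (b, a)
                if adj[mu][mu]:
                    w_c += pair_w(p, mu)
                    d_pair += 1
        return w_r, w_c, d_tri, d_pair

    override = params.fixation_override
    pop2 = 2.0 * params.pop_size
    eps = params.neutral_eps
    resync = params.resync_interval

    for step in range(params.n_mutations):
        idx = rng.randrange(n_pairs_total)
        a, b = pair_of[idx]
        linked = adj[a][b]
        sign = -1.0 if linked else 1.0

        w_r, w_c, d_tri, d_pair = flip_deltas(a, b)
        if a == b:
            dagg = g(deg[a] + (1 if not linked else -1)) - g(deg[a])
        else:
            step_d = 1 if not linked else -1
            dagg = (g(deg[a] + step_d) - g(deg[a])
                    + g(deg[b] + step_d) - g(deg[b]))

        if w_r == 0.0 and w_c == 0.0 and dagg == 0.0:
            r_mut = r_wt
            s = 0.0
        else:
            raw = r0 + b_r + sign * w_r + b_c + sign * w_c - (agg + dagg)
            r_mut = raw if raw > floor else floor
            s = 0.0 if r_mut == r_wt else math.log(r_mut) - log_r_wt

        if s > eps:
            cls = "beneficial"
        elif s < -eps:
            cls = "deleterious"
        else:
            cls = "neutral"
        tallies[cls] += 1

        if override is not None:
            prob = override
        elif -eps < s < eps:
            prob = 1.0 / pop2
        else:
            prob = fixation_probability(s, params.pop_size, eps)

        fixed = rng.random() < prob

        if fixed:
            new_val = 0 if linked else 1
            adj[a][b] = new_val
            adj[b][a] = new_val
            if a == b:
                deg[a] += 1 if new_val else -1
            else:
                d = 1 if new_val else -1
                deg[a] += d
                deg[b] += d
            n_links += 1 if new_val else -1
            n_tri += int(sign) * d_tri
            n_pair += int(sign) * d_pair
            # rebuild the cached wild-type decomposition from scratch;
            # fixations are rare, so exactness is cheap here
            net_now = _materialize(net.polymers, adj, n)
            r0, b_r, b_c, agg, n_tri, n_pair = _rate_components(
                net_now, state, params
            )
            r_wt = max(r0 + b_r + b_c - agg, floor)
            log_r_wt = math.log(r_wt)
            n_fixed += 1
            fixed_tallies[cls] += 1
            if new_val:
                n_fixed_adds += 1
                if is_copier[a] or is_copier[b]:
                    n_fixed_adds_copier += 1

        if log is not None:
            log["step"][step] = step
            log["node_a"][step] = a
            log["node_b"][step] = b
            log["action"][step] = "remove" if linked else "add"
            log["s"][step] = s
            log["fix_prob"][step] = prob
            log["fixed"][step] = fixed
            log["r_wt"][step] = r_wt
            log["r_mut"][step] = r_mut
            log["n_links"][step] = n_links
            log["n_tri"][step] = n_tri
            log["n_pairs"][step] = n_pair

        if resync and (step + 1) % resync == 0:
            net_now = _materialize(net.polymers, adj, n)
            chk = _rate_components(net_now, state, params)
            for cached, fresh, name in zip(
                (r0, b_r, b_c, agg, n_tri, n_pair), chk,
                ("r0", "boost_R", "boost_C", "aggregation", "n_tri", "n_pairs"),
            ):
                if not math.isclose(cached, fresh, rel_tol=1e-9, abs_tol=1e-12):
                    raise RuntimeError(
                        f"incremental {name} drifted: {cached!r} != {fresh!r}"
                    )
            r0, b_r, b_c, agg, n_tri, n_pair = chk
            r_wt = max(r0 + b_r + b_c - agg, floor)
            log_r_wt = math.log(r_wt)

    final_net = _materialize(net.polymers, adj, n)
    return TrajectoryRecord(
        seed=params.rng_seed,
        initial_network=network.copy(),
        final_network=final_net,
        n_mutations=params.n_mutations,
        n_beneficial=tallies["beneficial"],
        n_neutral=tallies["neutral"],
        n_deleterious=tallies["deleterious"],
        n_fixed=n_fixed,
        n_fixed_beneficial=fixed_tallies["beneficial"],
        n_fixed_neutral=fixed_tallies["neutral"],
        n_fixed_deleterious=fixed_tallies["deleterious"],
        n_fixed_adds=n_fixed_adds,
        n_fixed_adds_copier=n_fixed_adds_copier,
        initial_link_count=initial_links,
        final_link_count=final_net.link_count(),
        final_r_wt=r_wt,
        log=log,
    )


def _materialize(polymers, adj_rows, n) -> PIINetwork:
    arr = np.frombuffer(b"".join(bytes(r) for r in adj_rows), dtype=np.uint8)
    return PIINetwork(polymers, arr.reshape(n, n).copy())


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Mean/SD statistics over independent trajectories."""

    n_trajectories: int
    seeds: list[dict[str, int]]
    initial_links_mean: float
    initial_links_sd: float
    final_links_mean: float
    final_links_sd: float
    initial_links_per_node_mean: float
    final_links_per_node_mean: float
    initial_mean_degree_mean: float
    initial_mean_degree_sd: float
    final_mean_degree_mean: float
    final_mean_degree_sd: float
    frac_beneficial_mean: float
    frac_neutral_mean: float
    frac_deleterious_mean: float
    frac_fixed_adds_copier_mean: float
    n_fixed_mean: float

    def to_json(self, path=None) -> str:
        from dataclasses import asdict

        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def spawn_trajectory_seeds(master_seed: int, n_trajectories: int) -> list[dict[str, int]]:
    """Deterministic per-trajectory child seeds from one master seed.

    Each trajectory gets independent 31-bit seeds for network generation,
    copier-effectiveness draws and the mutation loop, derived through
    numpy's SeedSequence spawning so trajectories are statistically
    independent yet fully reproducible.
    """
    ss = np.random.SeedSequence(master_seed)
    out = []
    for child in ss.spawn(n_trajectories):
        g, e, t = (int(x) % (2**31) for x in child.generate_state(3))
        out.append({"network": g, "effectiveness": e, "trajectory": t})
    return out


def run_ensemble(
    n_trajectories: int,
    generator_params: dict,
    state_params: dict,
    params: EvolutionParams,
    master_seed: int = 0,
    return_records: bool = False,
):
    """Independent trajectories from freshly generated initial networks.

    ``generator_params`` are keyword arguments for
    :func:`piinet.network.generate_initial_network` (minus ``rng_seed``);
    ``state_params`` are kinetic keyword arguments for
    :meth:`ProtocellState.for_network` (minus ``rng_seed``).  Per-trajectory
    seeds are spawned deterministically from ``master_seed``.
    """
    from .network import generate_initial_network
    from dataclasses import replace as _replace

    if n_trajectories < 1:
        raise ParameterError("n_trajectories must be >= 1")
    seeds = spawn_trajectory_seeds(master_seed, n_trajectories)
    records = []
    for seed_set in seeds:
        net = generate_initial_network(
            rng_seed=seed_set["network"], **generator_params
        )
        st = ProtocellState.for_network(
            net, rng_seed=seed_set["effectiveness"], **state_params
        )
        traj_params = _replace(
            params, rng_seed=seed_set["trajectory"], keep_log=False
        )
        records.append(run_trajectory(net, st, traj_params))

    summary = summarize_ensemble(records, seeds)
    if return_records:
        return summary, records
    return summary


def summarize_ensemble(
    records: list[TrajectoryRecord], seeds: list[dict[str, int]]
) -> EnsembleSummary:
    def mean_sd(values):
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    n_nodes = records[0].initial_network.n_nodes
    init_links, init_links_sd = mean_sd([r.initial_link_count for r in records])
    fin_links, fin_links_sd = mean_sd([r.final_link_count for r in records])
    init_deg, init_deg_sd = mean_sd(
        [r.initial_network.degrees().mean() for r in records]
    )
    fin_deg, fin_deg_sd = mean_sd(
        [r.final_network.degrees().mean() for r in records]
    )
    frac_b, _ = mean_sd([r.n_beneficial / r.n_mutations for r in records])
    frac_n, _ = mean_sd([r.n_neutral / r.n_mutations for r in records])
    frac_d, _ = mean_sd([r.n_deleterious / r.n_mutations for r in records])
    copier_fracs = [
        r.n_fixed_adds_copier / r.n_fixed_adds
        for r in records
        if r.n_fixed_adds > 0
    ]
    frac_copier = float(np.mean(copier_fracs)) if copier_fracs else float("nan")
    n_fixed_mean, _ = mean_sd([r.n_fixed for r in records])

    return EnsembleSummary(
        n_trajectories=len(records),
        seeds=seeds,
        initial_links_mean=init_links,
        initial_links_sd=init_links_sd,
        final_links_mean=fin_links,
        final_links_sd=fin_links_sd,
        initial_links_per_node_mean=init_links / n_nodes,
        final_links_per_node_mean=fin_links / n_nodes,
        initial_mean_degree_mean=init_deg,
        initial_mean_degree_sd=init_deg_sd,
        final_mean_degree_mean=fin_deg,
        final_mean_degree_sd=fin_deg_sd,
        frac_beneficial_mean=frac_b,
        frac_neutral_mean=frac_n,
        frac_deleterious_mean=frac_d,
        frac_fixed_adds_copier_mean=frac_copier,
        n_fixed_mean=n_fixed_mean,
    )
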