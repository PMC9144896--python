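"""Growth-rate laws: reference rate, ODE splitting time, boosts, aggregation."""

import itertools

import numpy as np
import pytest

from piinet import (
    AggregationParams,
    ProtocellState,
    aggregation_cost,
    copier_rate_boost,
    elongation_derivatives,
    reference_growth_rate,
    reference_volume,
    splitting_time_numeric,
    total_growth_rate,
)
from piinet.network import Direction, MutationEvent, apply_mutation

from conftest import build_network


def unit_state(net, **kw):
    kw.setdefault("alpha", {r: 0.0 for r in net.ribosome_nodes})
    kw.setdefault("beta", {p: 0.0 for p in net.polymerase_nodes})
    return ProtocellState.for_network(net, **kw)


class TestReferenceQuantities:
    def test_volume_is_sum_of_chain_volumes(self):
        net = build_network("FRPI", [10, 1, 1, 1], [])
        st = unit_state(net)
        assert reference_volume(st, net) == 13.0
        heavier = unit_state(net, v_F=2.0)
        assert reference_volume(heavier, net) == 2 * 12 + 1.0

    def test_volume_linear_in_copy_numbers(self):
        net = build_network("FRPI", [10, 4, 6, 30], [])
        v1 = reference_volume(ProtocellState(copies=[1, 1, 1, 1]), net)
        v2 = reference_volume(ProtocellState(copies=[2, 2, 2, 2]), net)
        assert v2 == 2 * v1

    def test_reference_rate_worked_example(self):
        # two functional types (L=10, 20), one informational (L=30),
        # unit copies and rates: r0 = 3 / 60 = 0.05
        net = build_network("RPI", [10, 20, 30], [])
        st = unit_state(net)
        assert reference_growth_rate(st, net) == pytest.approx(0.05, abs=0)

    def test_rate_scales_inversely_with_lengths(self):
        net_a = build_network("RPII", [10, 20, 30, 12], [])
        net_b = build_network("RPII", [30, 60, 90, 36], [])
        st_a, st_b = unit_state(net_a), unit_state(net_b)
        assert reference_growth_rate(st_a, net_a) == pytest.approx(
            3 * reference_growth_rate(st_b, net_b)
        )


class TestElongation:
    def test_no_catalysis_recovers_baseline_rates(self):
        net = build_network("FRIP", [12, 8, 12, 6], [(0, 1), (1, 2), (0, 2)])
        st = unit_state(net, k_F=2.0, k_I=3.0)
        d = elongation_derivatives(st, net, st.copies)
        assert d[0] == pytest.approx(2.0 / 12)
        assert d[1] == pytest.approx(2.0 / 8)
        assert d[2] == pytest.approx(3.0 / 12)

    def test_translation_triangle_term(self):
        # single triangle, unit copies, alpha=0.5, L_j=10, k_F=1:
        # dn_j/dt = 1/10 + 0.5 = 0.6
        net = build_network("FRIP", [10, 8, 10, 6], [(0, 1), (1, 2), (0, 2)])
        st = unit_state(net, alpha={1: 0.5})
        d = elongation_derivatives(st, net, st.copies)
        assert d[0] == pytest.approx(0.6)

    def test_replication_pair_term(self):
        # single pair, n_P=1, m_mu=2, beta=0.25, L_mu=10, k_I=1:
        # dm_mu/dt = 0.1 + 0.25 * 1 * 4 = 1.1
        net = build_network("RPI", [8, 6, 10], [(1, 2), (2, 2)])
        st = ProtocellState(
            copies=[1, 1, 2], alpha={0: 0.0}, beta={1: 0.25}
        )
        d = elongation_derivatives(st, net, st.copies)
        assert d[2] == pytest.approx(1.1)

    def test_incomplete_subgraph_contributes_nothing(self):
        net = build_network("FRIP", [10, 8, 10, 6], [(0, 1), (1, 2)])
        st = unit_state(net, alpha={1: 0.9}, beta={3: 0.9})
        d = elongation_derivatives(st, net, st.copies)
        assert d[0] == pytest.approx(0.1)


class TestSplittingTime:
    def test_linear_growth_closed_form(self):
        # alpha=beta=0: V grows linearly, T_s = V0 / (vF kF N_F + vI kI N_I);
        # 3 types with V0=60 and unit v, k -> T_s = 20 exactly
        net = build_network("RPI", [10, 20, 30], [])
        st = unit_state(net)
        ts, rate = splitting_time_numeric(st, net)
        assert ts == pytest.approx(20.0, rel=1e-8)
        assert rate == pytest.approx(reference_growth_rate(st, net), rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_splitting_time_equals_r0_without_catalysis(self, seed):
        rng = np.random.default_rng(seed)
        lengths = [int(x) for x in rng.integers(5, 26, size=6)]
        copies = [int(x) for x in rng.integers(1, 4, size=6)]
        net = build_network("RPFFII", lengths, [])
        st = ProtocellState(
            copies=copies,
            k_F=float(rng.uniform(0.5, 3)),
            k_I=float(rng.uniform(0.5, 3)),
            v_F=float(rng.uniform(0.5, 2)),
            v_I=float(rng.uniform(0.5, 2)),
            alpha={0: 0.0},
            beta={1: 0.0},
        )
        _, rate = splitting_time_numeric(st, net)
        assert rate == pytest.approx(reference_growth_rate(st, net), rel=1e-8)

    def test_active_subgraph_strictly_shortens_splitting(self):
        net = build_network("FRIP", [10, 8, 10, 6],
                            [(0, 1), (1, 2), (0, 2), (3, 2), (2, 2)])
        st0 = unit_state(net)
        st1 = unit_state(net, alpha={1: 0.3}, beta={3: 0.3})
        ts0, _ = splitting_time_numeric(st0, net)
        ts1, _ = splitting_time_numeric(st1, net)
        assert ts1 < ts0


def symbolic_boost(net, st, triangles, pairs):
    """Independent oracle: first-order boost by symbolic integration of the
    catalytic volume production along the catalysis-free trajectory."""
    import sympy as sp

    t = sp.Symbol("t")
    lengths = net.lengths
    n_f = len(net.functional_nodes)
    n_i = len(net.informational_nodes)
    v0 = sp.Integer(0)
    for p in net.polymers:
        vx = st.v_F if p.is_functional else st.v_I
        v0 += sp.Rational(st.copies[p.id]) * vx * lengths[p.id]
    t0 = v0 / (st.v_F * st.k_F * n_f + st.v_I * st.k_I * n_i)

    def traj(node):
        p = net.polymers[node]
        k = st.k_F if p.is_functional else st.k_I
        return st.copies[node] + sp.Rational(k) / lengths[node] * t

    d_r = sp.Integer(0)
    for j, r, mu in triangles:
        avg = sp.integrate(traj(j) * traj(r) * traj(mu), (t, 0, t0)) / t0
        d_r += st.v_F * lengths[j] * sp.Rational(st.alpha[r]) * avg / v0
    d_c = sp.Integer(0)
    for p_node, mu in pairs:
        avg = sp.integrate(traj(p_node) * traj(mu) ** 2, (t, 0, t0)) / t0
        d_c += st.v_I * lengths[mu] * sp.Rational(st.beta[p_node]) * avg / v0
    return float(d_r), float(d_c)


class TestCopierBoost:
    def test_no_complete_subgraph_means_zero_boost(self):
        net = build_network("FRIP", [10, 8, 10, 6], [(0, 1), (1, 2)])
        st = unit_state(net, alpha={1: 0.9}, beta={3: 0.9})
        assert copier_rate_boost(st, net) == (0.0, 0.0)

    def test_single_triangle_matches_symbolic_oracle(self):
        # alpha=0.05, L_j=10, V0=30, unit copies: the cycle-averaged boost
        # exceeds the same product frozen at t=0 (copies grow over a cycle)
        net = build_network("FRIP", [10, 8, 10, 2],
                            [(0, 1), (1, 2), (0, 2)])
        st = unit_state(net, alpha={1: 0.05})
        d_r, d_c = copier_rate_boost(st, net)
        exp_r, exp_c = symbolic_boost(net, st, [(0, 1, 2)], [])
        assert d_r == pytest.approx(exp_r, rel=1e-12)
        assert d_c == exp_c == 0.0
        assert d_r > 10 * 0.05 / 30.0  # strictly above the frozen-copies value

    def test_boost_additive_over_disjoint_subgraphs(self):
        net = build_network(
            "FRIPFI",
            [10, 8, 10, 6, 14, 14],
            [(0, 1), (1, 2), (0, 2), (4, 1), (1, 5), (4, 5), (3, 2), (2, 2)],
        )
        st = unit_state(net, alpha={1: 0.4}, beta={3: 0.7})
        d_r, d_c = copier_rate_boost(st, net)
        exp_r, exp_c = symbolic_boost(
            net, st, [(0, 1, 2), (4, 1, 5)], [(3, 2)]
        )
        assert d_r == pytest.approx(exp_r, rel=1e-12)
        assert d_c == pytest.approx(exp_c, rel=1e-12)
        # additivity: each subgraph alone contributes its own weight
        only_first = symbolic_boost(net, st, [(0, 1, 2)], [])[0]
        only_second = symbolic_boost(net, st, [(4, 1, 5)], [])[0]
        assert d_r == pytest.approx(only_first + only_second, rel=1e-12)

    def test_perturbative_boost_tracks_ode_oracle(self):
        # r0 + boosts must agree with the numeric 1/T_s within 10% for
        # effectiveness up to 0.05 with unit copies, and the relative error
        # must shrink as the effectiveness shrinks
        net = build_network(
            "FRIP", [10, 8, 10, 6],
            [(0, 1), (1, 2), (0, 2), (3, 2), (2, 2)],
        )
        errors = []
        for eff in (0.05, 0.01, 0.001):
            st = unit_state(net, alpha={1: eff}, beta={3: eff})
            d_r, d_c = copier_rate_boost(st, net)
            r_pert = reference_growth_rate(st, net) + d_r + d_c
            _, r_exact = splitting_time_numeric(st, net)
            errors.append(abs(r_pert - r_exact) / r_exact)
        assert errors[0] < 0.10
        assert errors[0] > errors[1] > errors[2]


class TestAggregation:
    @pytest.mark.parametrize(
        "degree,expected", [(4, 0.0), (5, 0.025), (6, 0.03)]
    )
    def test_threshold_cost(self, degree, expected):
        params = AggregationParams(threshold_D=5, delta=0.005)
        assert params.cost(degree) == pytest.approx(expected)

    def test_cost_sums_over_all_nodes(self):
        # star center with degree 5 (incl. a self-loop) pays 0.025
        net = build_network(
            "RPIII", [5] * 5, [(0, 1), (0, 2), (0, 3), (0, 4), (0, 0)]
        )
        assert aggregation_cost(net, AggregationParams()) == pytest.approx(0.025)


class TestTotalRate:
    def test_quiet_network_reduces_to_r0(self):
        net = build_network("RPII", [10, 10, 10, 10], [(0, 2)])
        st = unit_state(net, alpha={0: 0.5}, beta={1: 0.5})
        gr = total_growth_rate(st, net, AggregationParams())
        assert gr.r_total == gr.r0
        assert gr.delta_r_R == gr.delta_r_C == gr.aggregation_penalty == 0.0

    def test_completing_a_triangle_raises_the_rate(self):
        net = build_network("FRIP", [10, 8, 10, 6], [(0, 1), (1, 2)])
        st = unit_state(net, alpha={1: 0.5})
        before = total_growth_rate(st, net, AggregationParams()).r_total
        after_net = apply_mutation(net, MutationEvent(0, 2, Direction.ADD))
        after = total_growth_rate(st, after_net, AggregationParams()).r_total
        assert after > before

    def test_crossing_the_threshold_lowers_the_rate(self):
        # node 0 at degree D-1=4; a new inert link activates g(k)
        net = build_network(
            "RPIIFI", [10] * 6, [(0, 1), (0, 2), (0, 3), (0, 4)]
        )
        st = unit_state(net)
        before = total_growth_rate(st, net, AggregationParams()).r_total
        after_net = apply_mutation(net, MutationEvent(0, 5, Direction.ADD))
        after = total_growth_rate(st, after_net, AggregationParams()).r_total
        assert after < before

    def test_rate_decomposition_identity(self):
        net = build_network(
            "FRIP", [10, 8, 10, 6],
            [(0, 1), (1, 2), (0, 2), (3, 2), (2, 2)],
        )
        st = unit_state(net, alpha={1: 0.2}, beta={3: 0.3})
        gr = total_growth_rate(st, net, AggregationParams())
        assert gr.r_total == pytest.approx(
            gr.r0 + gr.delta_r_R + gr.delta_r_C - gr.aggregation_penalty
        )

    def test_invariant_under_node_relabeling(self):
        roles, lengths = "FRIP", [10, 8, 10, 6]
        links = [(0, 1), (1, 2), (0, 2), (3, 2), (2, 2)]
        perm = [2, 0, 3, 1]  # new position of each old node
        r_roles = [None] * 4
        r_lengths = [None] * 4
        for old, new in enumerate(perm):
            r_roles[new] = roles[old]
            r_lengths[new] = lengths[old]
        r_links = [(perm[a], perm[b]) for a, b in links]
        net_a = build_network(roles, lengths, links)
        net_b = build_network("".join(r_roles), r_lengths, r_links)
        st_a = unit_state(net_a, alpha={1: 0.2}, beta={3: 0.3})
        st_b = unit_state(net_b, alpha={perm[1]: 0.2}, beta={perm[3]: 0.3})
        ga = total_growth_rate(st_a, net_a, AggregationParams())
        gb = total_growth_rate(st_b, net_b, AggregationParams())
        assert ga.r_total == pytest.approx(gb.r_total)

    def test_rate_monotone_in_effectiveness(self):
        net = build_network(
            "FRIP", [10, 8, 10, 6],
            [(0, 1), (1, 2), (0, 2), (3, 2), (2, 2)],
        )
        rates = [
            total_growth_rate(
                unit_state(net, alpha={1: a}, beta={3: a}),
                net,
                AggregationParams(),
            ).r_total
            for a in (0.0, 0.2, 0.5, 1.0)
        ]
        assert rates == sorted(rates) and len(set(rates)) == len(rates)

    def test_floor_keeps_rate_positive(self):
        # degrees far above threshold: raw rate would be negative
        n = 8
        links = [(a, b) for a in range(n) for b in range(a, n)]
        net = build_network("RPFFIIII", [10] * n, links)
        st = unit_state(net)
        gr = total_growth_rate(st, net, AggregationParams(delta=1.0))
        assert 0 < gr.r_total < gr.r0
        assert np.isfinite(np.log(gr.r_total))
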