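"""Topology of a network before and after evolution.

Evolves a 20-type network under strong catalysis and compares degree,
betweenness and closeness centralities of the initial and final snapshots,
highlighting the copy-machine nodes.
"""

from piinet import (
    EvolutionParams,
    ProtocellState,
    generate_initial_network,
    run_trajectory,
    topology_profile,
)

net = generate_initial_network(
    10, 10, link_prob=0.08, length_range=(5, 12), rng_seed=5
)
state = ProtocellState.for_network(net, rng_seed=6)
rec = run_trajectory(
    net, state,
    EvolutionParams(pop_size=10_000, n_mutations=50_000, rng_seed=8),
)

for label, snapshot in (("initial", net), ("final", rec.final_network)):
    prof = topology_profile(snapshot)
    table = prof.per_node.sort_values("degree", ascending=False).head(5)
    print(f"\n{label} network — giant component fraction "
          f"{prof.giant_component_fraction:.2f}; top degrees:")
    print(table.to_string(index=False,
                          float_format=lambda x: f"{x:.3f}"))

print(
    "\nDegree counts a node's interactions, betweenness its share of\n"
    "shortest paths, closeness how near it sits to everything reachable.\n"
    "Copy machines that completed subgraphs climb this ranking as\n"
    "evolution proceeds."
)
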