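"""Growth rate of a single protocell, with and without copy machines.

Builds a four-type protocell (substrate protein, ribosome-like copier,
xNA, polymerase-like copier) holding one complete translation triangle and
one complete replication pair, and compares the perturbative growth rate
r0 + delta_r_R + delta_r_C against the exact inverse splitting time from
integrating the elongation ODEs until the volume doubles.
"""

import numpy as np

from piinet import (
    AggregationParams,
    PIINetwork,
    PolymerSpec,
    ProtocellState,
    Role,
    splitting_time_numeric,
    total_growth_rate,
)

polymers = (
    PolymerSpec(0, Role.FUNCTIONAL, length=10),      # substrate protein j
    PolymerSpec(1, Role.PROTEIN_COPIER, length=8),   # ribosome-like R
    PolymerSpec(2, Role.INFORMATIONAL, length=10),   # xNA mu (L matches j)
    PolymerSpec(3, Role.XNA_COPIER, length=6),       # polymerase-like P
)
adj = np.zeros((4, 4), dtype=np.uint8)
for a, b in [(0, 1), (1, 2), (0, 2), (3, 2), (2, 2)]:
    adj[a, b] = adj[b, a] = 1
net = PIINetwork(polymers, adj)

for eff in (0.0, 0.02, 0.05):
    state = ProtocellState.for_network(net, alpha={1: eff}, beta={3: eff})
    rates = total_growth_rate(state, net, AggregationParams())
    t_s, exact = splitting_time_numeric(state, net)
    print(
        f"effectiveness={eff:4.2f}  r0={rates.r0:.5f}  "
        f"dr_R={rates.delta_r_R:.5f}  dr_C={rates.delta_r_C:.5f}  "
        f"r_total={rates.r_total:.5f}  1/T_s(ODE)={exact:.5f}"
    )

print(
    "\nr0 is the splitting rate from baseline chain elongation alone; the\n"
    "copier boosts raise it in proportion to their effectiveness, and the\n"
    "perturbative total tracks the exact ODE splitting rate for small\n"
    "effectiveness (the gap is the higher-order autocatalytic runaway)."
)
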