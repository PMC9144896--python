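# Methods

## The model

`piinet` simulates the co-evolution of short functional polymers (peptides)
and informational polymers (xNAs — DNA or RNA) inside growing, dividing
protocells.  The state of the system is a *PII network*: one node per
molecular type, a symmetric binary adjacency matrix over the types
(self-loops allowed), a chain length and an initial copy number per type,
and two distinguished protein roles — ribosome-like *protein copiers* and
polymerase-like *xNA copiers*.  Sequences are never represented; the
foldamer physical chemistry that would determine which chains bind and
catalyze is absorbed into the network links, the elongation rate constants
and the copier effectiveness parameters.

Three processes drive the dynamics:

1. **Growth and splitting.**  Every chain of length `L` elongates at
   `k_X / L` (one monomer per constant time interval), so the droplet
   volume grows linearly at `A = v_F k_F N_F + v_I k_I N_I` and doubles in
   `T0 = V0 / A`.  The reference growth rate is `r0 = 1 / T0`.
   Incompletely synthesized chains are ignored for volume accounting
   (elongation is fast compared with the division cycle).  Copy numbers
   reset to their post-split values `n_j0`, `m_mu0` at each rate
   evaluation: rates are a property of the network and the composition,
   not of an inherited trajectory.

2. **Catalysis by copy machines.**  A complete translation triangle
   (substrate protein `j`, protein copier `R`, xNA `mu`, links `j–R`,
   `R–mu`, `j–mu`, and `L_j = L_mu` for the primitive one-to-one code)
   adds `alpha_R * n_j n_R m_mu` to `dn_j/dt`.  A complete replication
   pair (xNA copier `P`, xNA `mu`, link `P–mu` plus self-loop `mu–mu`)
   adds `beta_P * n_P m_mu^2` to `dm_mu/dt`.  Copier nodes are proteins,
   count toward `N_F`, and are excluded as translation substrates (a
   copier does not copy itself).  Effectiveness values `alpha, beta` are
   drawn once per copier node, uniformly from [0, 1], representing the
   catalytic accuracy of that machine population.

3. **Mutation, selection, drift.**  A mutation flips one uniformly chosen
   unordered node pair (diagonal included — the xNA self-loop is a real
   degree of freedom).  The mutant protocell's net rate is
   `r = r0 + dr_R + dr_C − sum_k g(k)` with aggregation cost
   `g(k) = delta * d(k)` for nodes whose link count `d(k)` reaches the
   threshold `D` (self-loops count once toward `d`).  Fitness is
   `log r`; the selection coefficient `s = log r_mut − log r_wt` enters
   Kimura's fixation probability `(1 − e^{−2s}) / (1 − e^{−4Ns})`, with
   the neutral limit `1 / (2N)` inside a window `|s| < neutral_eps`.  A
   Bernoulli draw decides fixation; fixed mutants become the wild type.
   The protocell population of size `N` never appears explicitly — the
   run operates in the strong-selection / weak-mutation regime where one
   mutation is in play at a time, and `N` enters only through the
   fixation formula.

## The first-order copier boost

The growth-rate gain of a complete subgraph is computed as a first-order
perturbation in the effectiveness.  Writing the catalytic volume
production along the *unperturbed* trajectory
`n_i(t) = n_i0 + (k_X / L_i) t`, the exact first-order change of the
splitting rate is

    dr_R = (v_F / V0) * sum_triangles L_j * alpha_R * <n_j n_R m_mu>,
    dr_C = (v_I / V0) * sum_pairs     L_mu * beta_P * <n_P m_mu^2>,

where `<.>` is the time average over one cycle `[0, T0]` — a cubic
polynomial integrated in closed form.  Copy numbers roughly double within
a cycle, so this average is about three times larger than the same product
frozen at `t = 0`; freezing would systematically underestimate the boost
and was rejected after comparison with the exact dynamics.  The exact
splitting time (`splitting_time_numeric`) integrates the full nonlinear
ODE system with `scipy.integrate.solve_ivp` (RK45, relative tolerance
1e-10 by default) and locates the volume-doubling instant by the
integrator's event root-finding; it serves as the validation oracle.
Measured agreement on a four-type fixture with one triangle and one pair
(`examples/01_growth_rates.py`): 3.8% relative at effectiveness 0.05 and
0.9% at 0.02, with the error verified to keep shrinking down to
effectiveness 0.001 in the test suite.  The residual is the
higher-order autocatalytic runaway (the `m^2` replication term
self-amplifies), which grows with `effectiveness × T0`; the perturbative
formula should not be trusted for `alpha, beta ≳ 0.1` on slow-dividing
compositions, which is why the simulator's rate law is first-order by
construction rather than by truncation of a measured trajectory.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `n_functional`, `n_informational` | 25, 25 | types | fixed 50-type universe, split evenly |
| `n_ribosome`, `n_polymerase` | 1, 1 | nodes | one copy-machine type of each kind |
| `link_prob` | 0.05 | — | per-pair link probability at generation (1275 pairs → ≈ 64 links) |
| `length_min..length_max` | 5..25 | monomers | chain lengths, uniform; short chains per the foldamer picture, broad enough that `L_j = L_mu` coincidences are uncommon |
| `initial_copies` | 1 | chains | post-split copy number per type |
| `k_F`, `k_I` | 1, 1 | monomers/time | elongation rate constants (set the time unit) |
| `v_F`, `v_I` | 1, 1 | volume/monomer | monomer volumes |
| `D` | 5 | links | aggregation threshold |
| `delta` | 0.005 | rate | aggregation cost scale per link |
| `pop_size` | 100,000 | protocells | population in the fixation formula |
| `n_mutations` | 1,000,000 | — | proposed flips per trajectory |
| `n_trajectories` | 7 | — | independent replicates |
| `neutral_eps` | 1e-12 | — | neutral window on s (float-noise guard only: flips that change no subgraph and no aggregation term give bit-identical rates, hence s exactly 0) |

`r_total` is floored at `1e-12 * r0` so log-fitness is always defined; a
mutant at the floor is effectively dead (fixation ≈ 0 against any viable
wild type), and two floored rates compare as exactly neutral.

## The aggregation-dominated default regime

A consequence of the default calibration worth stating plainly: with
`k = v = 1` and lengths 5–25, `r0 ≈ 50/750 ≈ 0.067`, while a freshly
generated network at `link_prob = 0.05` typically carries five or six
nodes at degree ≥ 5, for an initial aggregation cost of ≈ 0.15.  Most
initial networks therefore start *below* the viability floor, where every
single flip is neutral (both rates sit at the floor) and the dynamics are
pure drift at fixation probability `1/(2N) = 5e-6`.  Networks whose
initial cost deficit is within one or two link-removals of viability
climb out quickly — the first relief removal that lifts the rate off the
floor carries an enormous `s` and fixes on arrival — and then evolve by
the ratchet: aggregation pruning first, copier-subgraph completions
after.  Across a default seven-trajectory ensemble both regimes occur.
Two observable consequences: (a) final network sizes stay close to
initial sizes (with `N = 100,000`, deleterious flips essentially never
fix, and only a handful of neutral fixations occur per million
proposals, so there is no mechanism for large net growth); and (b) the
fraction of proposals classified neutral is high but seed-dependent,
since floored trajectories classify everything as neutral while viable
trajectories see a substantial deleterious fraction from the aggregation
threshold.  Users wanting vigorous network growth should raise `k_X`
(faster division shrinks the relative weight of `delta`) or lower
`delta`; the defaults are kept as the study conditions.

## Simulation engine

Each proposal needs the mutant rate, but a single flip can only create or
destroy copier subgraphs containing the flipped pair and only changes the
degrees of its two endpoints.  The engine therefore precomputes the
first-order weight of every *possible* subgraph (weights depend only on
the composition, not the adjacency) and evaluates each proposal in O(k)
where k is the number of candidate third nodes — O(1) for most role
combinations.  The cached wild-type rate decomposition is rebuilt from
scratch at every fixation (fixations are rare) and cross-checked against
a full recomputation every 10,000 steps to 1e-9 relative, resynchronizing
so float drift can never accumulate.  Flips that change no subgraph and
no aggregation term short-circuit to `s = 0` exactly.

Randomness: network generation and effectiveness draws use
`numpy.random.default_rng`; the mutation loop uses `random.Random` (much
lower per-call overhead).  A master seed spawns per-trajectory triples of
31-bit child seeds (network, effectiveness, trajectory) through
`numpy.random.SeedSequence`, so ensembles are reproducible end-to-end and
trajectories are statistically independent.  A full seven-trajectory
default ensemble runs in well under a minute on one CPU.

## The synthetic generator and what passing tests mean

`generate_initial_network` emulates the study's starting condition: an
Erdős–Rényi-like draw over all unordered pairs including self-pairs, then
removal of uniformly chosen links from complete copier subgraphs until
none remain (evolution must *discover* the machines; at the default
sparsity this removes a small fraction of a link on average, barely
perturbing the ensemble).  The generator makes no attempt to emulate
sequence-level chemistry, realistic length distributions, monomer
depletion, spatial structure, or lipid-surface physics of division — so
tests passing against it demonstrate the correctness of the network
dynamics and selection arithmetic, not that any real prebiotic system
behaved this way.

## Numerical choices

- Kimura formula via `expm1`; for `|4Ns| > 700` the asymptotic branches
  are used (s > 0: `1 − e^{−2s}`; s < 0: evaluated in log space,
  underflowing gracefully to 0).  The function is strictly increasing in
  `s` throughout the float-representable range and continuous across the
  neutral window to within `(2N−1)·neutral_eps` relative.
- ODE splitting time: RK45 with rtol 1e-10, terminal event on
  `V(t) = 2 V0`, integration horizon 20 reference cycles (the
  catalysis-free limit then reduces to the closed form `T0 = V0 / A`
  to solver tolerance).
- Betweenness is Freeman's normalized shortest-path form and closeness
  the Wasserman–Faust component-scaled form (both via networkx);
  self-loops are excluded from all path metrics but count once toward
  degree, matching the aggregation convention.  Giant-component ties
  break toward the component containing the lowest node id.
- Trajectory logs are preallocated numpy columns (≈ 45 MB per million
  steps); ensembles drop per-step logs and keep summaries.

## Known limitations

- The population is implicit; clonal interference, standing variation
  and mutation-rate effects are outside the model by construction.
- The perturbative boost is first-order; strongly effective copiers on
  slow-dividing compositions are outside its validity range (the ODE
  oracle remains available for spot checks).
- Copy numbers reset each generation; there is no inheritance of
  intracellular composition.
- Nodes are never created or destroyed; the type universe is fixed.
- Aggregation is a mean-field threshold cost, not a physical model of
  polymer condensation.
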