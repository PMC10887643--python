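# Methods

## Model

`sicspread` implements a discrete-time SIC (Susceptible–Infected–Completed)
process for `M` interacting one-shot contagions on an undirected, unweighted
network of `N` nodes. Per contagion `k`, every node carries one compartment
`S_k → I_k → C_k`; `C` is absorbing and, unlike SIR's recovered state,
feeds back into the dynamics: a completed item keeps influencing the node's
willingness to adopt other items.

One synchronous step, evaluated entirely on the time-`t` configuration:

1. **Transmission.** Every infectious neighbour transmits item `k`
   independently with the per-edge rate `β_k`, so node `i` receives `k`
   with probability `f_i^(k) = 1 − Π_j (1 − β_k A_ji s_j^(k))`, where
   `s_j^(k)` indicates neighbour `j` is infectious with `k`.
2. **Interaction.** The adoption probability is modified by every item the
   node already holds or has completed: each competitive partner multiplies
   it by `(1 − a1)`, each cooperative partner by `(1 + a2)`. Because `a2`
   is unbounded, the modified probability is capped at 1
   (`g = min(1, f · modifier)`).
3. **Adoption.** One adoption candidate fires per susceptible coordinate,
   independently, with probability `g_k`. All fired items are adopted
   simultaneously — except that each *competitive pair* fired in the same
   step suppresses the joint adoption by a further `(1 − a1)`; suppressed
   mass adopts nothing. (See *Design choices*.)
4. **Completion.** Every coordinate that was infectious at time `t` flips
   to `C` with probability `γ_k`, independently; an item adopted in this
   step cannot complete in the same step.

The canonical three-item scenario (`three_contagion_preset`) has items 1
and 3 cooperating while item 2 competes with both; all competitive pairs
share the single inhibiting factor `a1 ∈ [0, 1]`, all cooperative pairs the
single enhancement factor `a2 ≥ 0`. Internally factors are resolved
per-pair from the relation matrix, so heterogeneous structures are
expressible programmatically; the CLI deliberately exposes only the two
scalars.

## Engines

**MMCA engine** (`mmca`). Tracks per node a probability vector over the
`3^M` joint compartments and iterates the step above as a deterministic
recursion, replacing the binary neighbour indicators in `f_i^(k)` by their
time-`t` marginal probabilities (the standard first-order mean-field
closure; neighbour states are treated as independent). Mass is routed
source-state-locally: for each joint state the adoption-subset and
completion-subset outcomes partition probability exactly, so row sums stay
at 1 to machine precision for any parameter values — this is asserted after
every step.

**Verbatim mode.** For audit purposes the engine can also iterate a literal
transcription of the printed 27-equation transition system of the
three-item model. The printed system is kept as printed, including its
idiosyncrasies: one inflow term names the wrong reception probability, one
cooperative inflow lacks its `(1 + a2)` boost, the all-completed state
lacks its self-retention term, and the `I1C2I3` state has no printed
equation at all (it is synthesised from the uniform rule so that the state
is not silently deleted — a transcription cannot assign it zero without
destroying mass). The all-susceptible state receives the residual
`1 − (sum of all other states)`; a negative residual (which large `a2` can
produce, since the printed weights are unclipped) raises a diagnostic error
rather than being silently renormalised. Verbatim mode is not
mass-conserving in general and is excluded from the quantitative claims.

**Stochastic simulator** (`simulate`). The identical process with hard
labels and exact binary neighbour counts: `f = 1 − (1 − β)^(#infectious
neighbours)`. Simultaneous adoption candidates are resolved by a collision
policy: `independent` (default — the exact stochastic counterpart of the
MMCA routing above), `reject` (ties adopt nothing) and `priority`
(lowest-index item wins, the reception-priority reading of the state
diagram). Runs end early at infectious extinction. All randomness flows
through an injected `numpy` Generator; identical seeds give bit-identical
trajectories.

**Exact master equation.** For instances with `(3^M)^N ≤ 10^4` the full
Markov chain over global configurations is evolved with the same per-node
kernel as the simulator. It is the ground truth that the Monte Carlo
sampler must approach at the `1/√n` rate, and the yardstick for how far the
MMCA closure deviates on graphs with strong local correlations.

**Threshold analysis** (`threshold`). Linearising the consistent-mode
recursion at the spreading-free state decouples items; the per-step growth
factors are `(1 − γ_k) + β_k λ` (infection modes), `(1 − γ_j)(1 − γ_k)`
(pair modes) and `(1 − γ_k)` (completion modes), with `λ` the adjacency
spectral radius. Stability — extinction of every item — holds iff all
magnitudes are below 1, i.e. `β_k/γ_k < 1/λ`; the interaction factors drop
out of the linearisation (they multiply second-order terms), which
`numerical_jacobian_radius` confirms by finite differences of the actual
update. `γ_k = 0` leaves that item's threshold undefined (an infectious
node never completes) and is reported explicitly as an infinite critical
rate with a warning rather than silently.

## Parameters and defaults

| parameter | meaning | range | default |
| --- | --- | --- | --- |
| `β_k` | per-edge, per-step transmission probability | [0, 1] | scenario-specific (0.1–0.3) |
| `γ_k` | per-step completion (I→C) probability | [0, 1] | 0.5 in all experiment presets |
| `a1` | competitive inhibition per held rival | [0, 1] | 0 |
| `a2` | cooperative enhancement per held partner | [0, ∞) | 0 |
| seeds | initially infectious nodes per item | — | 5, drawn independently per item |
| `n`, `m` | BA network size / attachment | — | 300 (desk scale) or 1000, `m = 3` |

The experiment scenarios fix only the transmission rates; the completion
rate is a package-wide choice. `γ = 0.5` (mean spreading lifetime of two
steps) was chosen once as a realistic mid-range value for short-lived
one-shot content and is used everywhere, including the threshold
experiments — the threshold location scales as `γ/λ`, so no qualitative
conclusion depends on this choice.

Sweep grids default to `a1 ∈ {0, 0.25, 0.5, 0.75, 1}`,
`a2 ∈ {0, 0.5, 1, 1.5, 2}`, `m ∈ {1, 3, 5}`. Within one sweep the seed
nodes are drawn once and reused at every grid value; varying the factor
while redrawing initial conditions would confound the comparison (this
matters: with redrawn seeds the coexistence trend is visibly non-monotone
at n = 300).

## Synthetic networks

`generate_ba(n, m, seed)` grows a Barabási–Albert graph from `m` isolated
nodes; each new node attaches to `m` distinct existing nodes with
probability proportional to degree plus a small constant (which makes the
degenerate all-zero start well defined). The edge count is therefore
exactly `m(n − m)`. This emulates the heavy-tailed degree structure of
follower networks — hubs, short paths, λ well above the mean degree — but
none of their other features: no clustering beyond what preferential
attachment induces, no communities, no degree correlations, no directed
follower/followee asymmetry. Passing tests on these graphs therefore
validates the dynamics and the spectral theory, not any claim about a
specific real platform. Real networks enter through plain-text edge lists
(`read_edgelist`; 0-based integer ids, `#` comments).

## Numerical choices

- Reception probabilities are computed in log space
  (`1 − exp(Σ log1p(−βq))`) so that products over hundreds of neighbours
  neither underflow nor lose precision; a certain transmission (`βq = 1`)
  yields `f = 1` exactly via `−inf` in the log sum.
- MMCA convergence: iteration stops when the largest per-entry change falls
  below `tol` (default 1e−9; the dynamics are absorbing so this coincides
  with infectious extinction) or at `max_steps` (default 5000).
- Spectral radius: dense symmetric eigendecomposition up to 64 nodes,
  Lanczos (`eigsh`, largest-algebraic) above; disconnected input warns and
  refers to the full graph; an empty edge set returns 0 with a warning.
- Joint states are encoded base-3 with item 0 least significant
  (`S=0, I=1, C=2`), so adoption adds `3^k` and completion adds `3^k`
  again — transition targets are pure integer offsets.
- The sweep driver gives every grid point a deterministic child RNG stream,
  so any single point is reproducible in isolation from the stored
  manifest.

## Design choices

**Simultaneous adoption.** The printed three-item transition system routes
no probability from the all-susceptible state into doubly-infected states:
a node can adopt at most one item per step, and simultaneous receptions
are discarded. That rule couples items even when all relations are neutral,
which contradicts the model's own premise that neutral items spread
independently (and breaks the factorisation of the joint dynamics into
single-item chains that the neutral case should satisfy exactly). The
consistent mode therefore adopts all simultaneously fired items, with one
refinement: a simultaneously fired competitive pair is suppressed by the
same `(1 − a1)` factor that governs sequential adoption, so complete
competition (`a1 = 1`) excludes joint engagement exactly — whether the
rival arrives a step later or in the same step. Cooperative boosts apply
only from items already held or completed, never between two simultaneous
receptions: a boost there would inflate the outcome weights above total
probability 1 for large `a2`, and "enhancement by an item the node does not
yet hold" has no behavioural reading.

**Completed states influence like infectious ones.** Both `I` and `C`
partners contribute their `(1 ± a)` factor to the adoption modifier: the
memory of having spread an item, not the act of spreading it, is what
biases further adoptions.

**Directedness.** The transmission equations accept a directed adjacency
(column `i` lists the in-neighbours that can reach `i`), but the threshold
analysis refuses directed networks: the spectral argument rests on the
symmetry (Perron–Frobenius) of the adjacency matrix.

**Seed protocol.** Each item's seed set is drawn independently, without
replacement within the item; a node seeded by several items starts jointly
infectious with all of them. Ensembles redraw seeds each repetition by
default (matching a protocol of "randomly select initial nodes per
experiment"); fixed-seed repetition is available.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the full suite completes in a few minutes on one CPU: BA networks of
50–300 nodes (1000 in the README example), 10⁴–10⁵ stochastic runs where a
sampling distribution is compared against the exact chain, 20–50 randomized
parameter draws for conservation checks. Paper-scale sweeps (n = 1000, 100
repetitions, 5 seeds per item) are available behind `--paper-scale` and the
`preset_spec(..., n=1000)` argument.

## Known limitations

- The MMCA closure assumes neighbour independence; on small dense graphs
  or graphs with strong clustering it overestimates spread near the
  threshold. The master-equation oracle quantifies this on tiny instances;
  no tight MMCA-versus-simulation bound is claimed.
- Near the threshold (`β = 0.9 γ/λ`) the subcritical transient still
  engages on the order of `deg × seeds × 10` nodes before extinction; on a
  300-node network this is several per cent of the population, so "final
  spread ≈ seed fraction" holds only loosely at small `n` (and sharpens as
  `n` grows). The acceptance suite documents this with an intentionally
  strict assertion at n = 300 that records the measured excess.
- No continuous-time (Gillespie) dynamics, no pair-approximation closure,
  no weighted or temporal networks, no directed threshold theory.
- Verbatim mode exists for auditability only; its non-conservation makes
  it unsuitable for quantitative use.
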