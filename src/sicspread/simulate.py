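"""Discrete-time synchronous agent-based simulation of the SIC process.

Each node holds a hard compartment label per contagion (S=0, I=1, C=2).
Updates are synchronous and all evaluated on the time-t configuration: an
infectious node transmits along each incident edge independently with
probability beta_k and may complete (I -> C, probability gamma_k) in the
same step. A susceptible coordinate draws an adoption *candidate* with the
interaction-modified reception probability; simultaneous candidates are
resolved by the collision policy:

``independent`` (default)
    adopt every fired contagion, except that a set containing competitive
    pairs survives only with probability ``(1 - a1)`` per such pair
    (otherwise nothing is adopted) — the exact stochastic counterpart of
    the MMCA engine's consistent mode;
``reject``
    adopt only when exactly one candidate fires, ties adopt nothing;
``priority``
    adopt the lowest-index fired contagion (the reception-priority reading
    of the transition diagram).

For tiny instances :func:`exact_master_equation` evolves the exact Markov
chain over all ``(3^M)^N`` global configurations with the identical per-node
kernel, serving as the ground-truth oracle for the Monte Carlo sampler.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .mmca import Trajectory, competitive_suppression
from .model import (
    C,
    I,
    InteractionModel,
    RateParams,
    S,
    effective_adoption_probability,
    modifier_table,
    n_states,
    state_table,
)
from .network import Network, ParameterError


@dataclass
class SimulationState:
    """Hard labels: ``labels[i, k]`` is node i's compartment for contagion k."""

    labels: np.ndarray  # (N, M) int, values in {0, 1, 2}
    step: int = 0

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def M(self) -> int:
        return self.labels.shape[1]

    def any_infectious(self) -> bool:
        return bool((self.labels == I).any())

    def fractions(self) -> np.ndarray:
        """(M, 3) compartment fractions."""
        out = np.empty((self.M, 3))
        for comp in (S, I, C):
            out[:, comp] = (self.labels == comp).mean(axis=0)
        return out


def initial_state(net: Network, seeds) -> SimulationState:
    if isinstance(seeds, dict):
        m = max(seeds) + 1 if seeds else 1
        seeds = [list(seeds.get(k, [])) for k in range(m)]
    labels = np.zeros((net.n, len(seeds)), dtype=np.int64)
    for k, nodes in enumerate(seeds):
        for v in nodes:
            if not 0 <= v < net.n:
                raise ParameterError(f"seed node {v} outside 0..{net.n - 1}")
            labels[v, k] = I
    return SimulationState(labels=labels)


def _node_modifiers(labels: np.ndarray, im: InteractionModel) -> np.ndarray:
    """(N, M) interaction multiplier for adopting each contagion now."""
    n, M = labels.shape
    mod = np.ones((n, M))
    engaged = labels != S  # I or C both count
    for j in range(M):
        ej = engaged[:, j]
        for k in range(M):
            if j == k:
                continue
            factor = im.pair_factor(j, k)
            if factor != 1.0:
                mod[ej, k] *= factor
    return mod


def mc_step(
    state: SimulationState,
    net: Network,
    rates: RateParams,
    im: InteractionModel,
    rng: np.random.Generator,
    collision_policy: str = "independent",
) -> SimulationState:
    """One synchronous stochastic update; consumes only the passed rng."""
    if collision_policy not in ("independent", "reject", "priority"):
        raise ParameterError(f"unknown collision policy {collision_policy!r}")
    labels = state.labels
    beta = rates.beta_array()
    gamma = rates.gamma_array()
    infectious = (labels == I).astype(float)  # (N, M)
    # reception probability from actual infectious neighbours:
    # f[i, k] = 1 - (1 - beta_k)^{#infectious in-neighbours}
    counts = net.adjacency.T @ infectious
    f = 1.0 - (1.0 - beta[None, :]) ** counts
    g = effective_adoption_probability(f, _node_modifiers(labels, im))
    g[labels != S] = 0.0

    candidates = rng.random(labels.shape) < g
    n_fired = candidates.sum(axis=1)
    new = labels.copy()
    if collision_policy == "independent":
        supp = np.ones(state.n)
        for j in range(state.M):
            for k in range(j + 1, state.M):
                factor = competitive_suppression((j, k), im)
                if factor != 1.0:
                    supp[candidates[:, j] & candidates[:, k]] *= factor
        accept = rng.random(state.n) < supp
        new[candidates & accept[:, None]] = I
    elif collision_policy == "reject":
        adopters = n_fired == 1
        if adopters.any():
            which = candidates[adopters].argmax(axis=1)
            new[np.flatnonzero(adopters), which] = I
    else:  # priority: lowest-index candidate wins
        adopters = n_fired >= 1
        if adopters.any():
            which = candidates[adopters].argmax(axis=1)
            new[np.flatnonzero(adopters), which] = I

    # completion applies to coordinates infectious at time t (a node adopted
    # this step cannot complete this step)
    flips = rng.random(labels.shape) < gamma[None, :]
    new[(labels == I) & flips] = C
    return SimulationState(labels=new, step=state.step + 1)


def mc_run(
    net: Network,
    rates: RateParams,
    im: InteractionModel,
    seeds,
    steps: int,
    rng: np.random.Generator,
    collision_policy: str = "independent",
    record: bool = True,
) -> Trajectory:
    """Single stochastic realisation; ends early once no node is infectious."""
    if steps < 1:
        raise ParameterError("steps must be >= 1")
    state = initial_state(net, seeds)
    frames = [state.fractions()] if record else None
    t = 0
    for t in range(1, steps + 1):
        if not state.any_infectious():
            t -= 1
            break
        state = mc_step(state, net, rates, im, rng, collision_policy)
        if record:
            frames.append(state.fractions())
    final = state.fractions()
    spread = final[:, I] + final[:, C]
    fractions = np.stack(frames) if record else np.stack([final])
    return Trajectory(fractions=fractions, spread_size=spread, steps=t, converged=not state.any_infectious())


def draw_seed_sets(net: Network, seed_count: int, M: int, rng: np.random.Generator) -> list:
    """Independent without-replacement seed draw per contagion."""
    if seed_count > net.n:
        raise ParameterError(f"seed_count {seed_count} exceeds node count {net.n}")
    return [rng.choice(net.n, size=seed_count, replace=False).tolist() for _ in range(M)]


def mc_ensemble(
    net: Network,
    rates: RateParams,
    im: InteractionModel,
    seed_count: int = 5,
    n_runs: int = 100,
    steps: int = 1000,
    rng: np.random.Generator = None,
    collision_policy: str = "independent",
    seeds=None,
    record: bool = False,
) -> tuple:
    """Ensemble of independent runs; returns (mean Trajectory, per-run spreads).

    By default each run redraws its seed nodes (*seed_count* per contagion,
    independently across contagions). Passing explicit *seeds* reuses the
    same seed sets in every run. The returned trajectory carries the mean
    compartment fractions (padded to the longest run) and the mean and
    standard error of the final spread size per contagion.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    runs = []
    spreads = np.empty((n_runs, im.M))
    for r in range(n_runs):
        run_seeds = seeds if seeds is not None else draw_seed_sets(net, seed_count, im.M, rng)
        traj = mc_run(net, rates, im, run_seeds, steps, rng, collision_policy, record=record)
        spreads[r] = traj.spread_size
        runs.append(traj)
    if record:
        longest = max(t.fractions.shape[0] for t in runs)
        acc = np.zeros((longest, im.M, 3))
        for t in runs:
            fr = t.fractions
            acc[: fr.shape[0]] += fr
            acc[fr.shape[0]:] += fr[-1]  # absorbed runs stay at their final state
        mean_fractions = acc / n_runs
    else:
        mean_fractions = np.stack([np.stack([t.fractions[-1] for t in runs]).mean(axis=0)])
    se = spreads.std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1 else np.zeros(im.M)
    mean_traj = Trajectory(
        fractions=mean_fractions,
        spread_size=spreads.mean(axis=0),
        steps=max(t.steps for t in runs),
        converged=all(t.converged for t in runs),
        se=se,
    )
    return mean_traj, spreads


# ---------------------------------------------------------------------------
# Exact master equation on tiny graphs
# ---------------------------------------------------------------------------

def _node_kernel(
    local: int,
    f: np.ndarray,
    gamma: np.ndarray,
    mod_row: np.ndarray,
    im: InteractionModel,
    collision_policy: str,
    M: int,
) -> dict:
    """Exact next-state distribution of one node given its reception probs.

    Mirrors :func:`mc_step`: independent adoption candidates with the
    modified probabilities, collision policy for simultaneous candidates,
    independent I -> C completion of time-t infectious coordinates.
    """
    codes = list(_decode(local, M))
    s_coords = [k for k in range(M) if codes[k] == S]
    i_coords = [k for k in range(M) if codes[k] == I]
    g = {k: min(1.0, f[k] * mod_row[k]) for k in s_coords}
    out = {}
    for fired in itertools.product([0, 1], repeat=len(s_coords)):
        p_f = 1.0
        for k, fl in zip(s_coords, fired):
            p_f *= g[k] if fl else 1.0 - g[k]
        if p_f == 0.0:
            continue
        fired_ks = [k for k, fl in zip(s_coords, fired) if fl]
        # (adopted set, probability share) branches of this fired pattern
        if not fired_ks:
            branches = [((), 1.0)]
        elif collision_policy == "independent":
            supp = competitive_suppression(fired_ks, im)
            branches = [(tuple(fired_ks), supp), ((), 1.0 - supp)]
        elif collision_policy == "reject":
            branches = [(tuple(fired_ks), 1.0)] if len(fired_ks) == 1 else [((), 1.0)]
        else:  # priority
            branches = [((min(fired_ks),), 1.0)]
        for adopted, p_branch in branches:
            if p_branch == 0.0:
                continue
            for flips in itertools.product([0, 1], repeat=len(i_coords)):
                p = p_f * p_branch
                nxt = list(codes)
                for k, fl in zip(i_coords, flips):
                    if fl:
                        p *= gamma[k]
                        nxt[k] = C
                    else:
                        p *= 1.0 - gamma[k]
                for k in adopted:
                    nxt[k] = I
                if p == 0.0:
                    continue
                t = _encode(nxt)
                out[t] = out.get(t, 0.0) + p
    return out


def _encode(codes) -> int:
    idx = 0
    for k, c in enumerate(codes):
        idx += c * 3 ** k
    return idx


def _decode(idx: int, M: int):
    for _ in range(M):
        yield idx % 3
        idx //= 3


def exact_master_equation(
    net: Network,
    rates: RateParams,
    im: InteractionModel,
    seeds,
    steps: int,
    collision_policy: str = "independent",
) -> np.ndarray:
    """Exact marginal compartment probabilities of the stochastic process.

    Evolves the full distribution over all ``(3^M)^N`` global configurations
    and returns an array of shape ``(steps + 1, N, M, 3)``: the probability
    that node *i* is in compartment S/I/C of contagion *k* at each step.
    Restricted to tiny instances (``(3^M)^N <= 10^4``).
    """
    M = im.M
    n_local = n_states(M)
    n_global = n_local ** net.n
    if n_global > 10_000:
        raise ParameterError(f"global state space {n_global} exceeds the 10^4 oracle limit")
    beta = rates.beta_array()
    gamma = rates.gamma_array()
    mod = np.nan_to_num(modifier_table(im), nan=0.0)
    codes_local = state_table(M)
    neighbor_lists = [net.neighbors(i) for i in range(net.n)]

    init = initial_state(net, seeds).labels
    start = sum(_encode(init[i]) * n_local ** i for i in range(net.n))
    dist = {start: 1.0}

    def node_locals(gstate: int) -> list:
        out = []
        for _ in range(net.n):
            out.append(gstate % n_local)
            gstate //= n_local
        return out

    def marg(d: dict) -> np.ndarray:
        m = np.zeros((net.n, M, 3))
        for g, p in d.items():
            for i, loc in enumerate(node_locals(g)):
                for k, c in enumerate(codes_local[loc]):
                    m[i, k, c] += p
        return m

    history = [marg(dist)]
    for _ in range(steps):
        nxt = {}
        for gstate, p in dist.items():
            locals_ = node_locals(gstate)
            infectious = (codes_local[locals_] == I).astype(float)  # (N, M)
            # per-node exact reception probabilities from the hard configuration
            kernels = []
            for i in range(net.n):
                counts = infectious[neighbor_lists[i]].sum(axis=0)
                f = 1.0 - (1.0 - beta) ** counts
                kernels.append(
                    _node_kernel(locals_[i], f, gamma, mod[locals_[i]], im, collision_policy, M)
                )
            # combine independent per-node kernels
            partial = {0: p}
            for i, kern in enumerate(kernels):
                scale = n_local ** i
                new_partial = {}
                for acc, pa in partial.items():
                    for loc, pl in kern.items():
                        key = acc + loc * scale
                        new_partial[key] = new_partial.get(key, 0.0) + pa * pl
                partial = new_partial
            for g2, p2 in partial.items():
                nxt[g2] = nxt.get(g2, 0.0) + p2
        dist = nxt
        history.append(marg(dist))
    return np.stack(history)
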