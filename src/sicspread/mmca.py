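"""Deterministic microscopic-Markov-chain (MMCA) engine.

The engine iterates, for every node, a probability vector over the ``3^M``
joint compartments of the M contagions. Neighbour influence enters through a
mean-field closure: the binary "neighbour j is infectious with k" indicator
of the exact process is replaced by its time-t marginal probability, so the
recursion is deterministic.

Two update modes are provided:

``consistent`` (default)
    Mass leaving each joint state is routed by three independent mechanisms
    evaluated on time-t quantities: (a) every I-coordinate completes (I -> C)
    with its rate ``gamma_k``; (b) for every S-coordinate an adoption
    candidate fires with the interaction-modified reception probability,
    candidates independent across contagions, and all fired contagions are
    adopted simultaneously — except that every *competitive* pair fired in
    the same step suppresses the joint adoption by a further ``(1 - a1)``
    (the suppressed mass adopts nothing); (c) C-coordinates are absorbing.
    Row sums stay exactly 1 by construction for any enhancement factor, the
    update factorises into independent single-contagion chains when all
    relations are neutral, and complete competition (``a1 = 1``) excludes
    joint engagement exactly, whether sequential or simultaneous.

``verbatim``
    A literal transcription of the printed three-contagion transition system
    (canonical relation preset only), kept for auditability. The printed
    system is not exactly mass-conserving; a negative residual raises a
    diagnostic error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import (
    C,
    I,
    InteractionModel,
    RateParams,
    Relation,
    S,
    effective_adoption_probability,
    modifier_table,
    n_states,
    parse_state_label,
    state_table,
)
from .network import Network, ParameterError


class ConsistencyError(RuntimeError):
    """The update produced an invalid probability distribution."""


@dataclass
class JointStateDistribution:
    """Per-node probability table over joint compartment states.

    ``P[i, s]`` is the probability that node *i* occupies joint state *s*
    (encoded base-3, contagion 0 least significant). Rows sum to 1.
    """

    P: np.ndarray
    M: int

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[1] != n_states(self.M):
            raise ParameterError(f"distribution must be (N, {n_states(self.M)}), got {self.P.shape}")
        self.validate()

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.P < -tol) or np.any(self.P > 1 + tol):
            raise ConsistencyError("probabilities outside [0, 1]")
        err = np.abs(self.P.sum(axis=1) - 1.0).max()
        if err > tol:
            raise ConsistencyError(f"row sums deviate from 1 by {err:.3e}")

    def compartment_marginals(self) -> np.ndarray:
        """(N, M, 3) per-node marginal probability of S/I/C per contagion."""
        codes = state_table(self.M)  # (3^M, M)
        out = np.empty((self.n, self.M, 3))
        for k in range(self.M):
            for comp in (S, I, C):
                out[:, k, comp] = self.P[:, codes[:, k] == comp].sum(axis=1)
        return out

    def infectious_marginal(self) -> np.ndarray:
        """(N, M) probability that each node is infectious with each contagion."""
        return self.compartment_marginals()[:, :, I]

    def copy(self) -> "JointStateDistribution":
        return JointStateDistribution(self.P.copy(), self.M)


@dataclass
class Trajectory:
    """Per-step compartment fractions and the final spread size.

    ``fractions[t, k]`` is the (S, I, C) fraction triple of contagion *k* at
    step *t* (step 0 is the initial condition). ``spread_size[k]`` is the
    final ever-engaged fraction (I + C marginal), the operational "proportion
    of individuals spreading" a contagion. ``se`` carries ensemble standard
    errors where applicable (zeros for deterministic runs).
    """

    fractions: np.ndarray  # (T+1, M, 3)
    spread_size: np.ndarray  # (M,)
    steps: int
    converged: bool
    se: np.ndarray = None

    def __post_init__(self):
        if self.se is None:
            self.se = np.zeros_like(self.spread_size)

    @property
    def M(self) -> int:
        return self.fractions.shape[1]


def reception_probabilities(net: Network, infectious_marginal: np.ndarray, beta) -> np.ndarray:
    """Per-node, per-contagion probability of receiving each contagion.

    ``f[i, k] = 1 - prod_j (1 - beta_k * A[j, i] * q[j, k])`` where ``q`` is
    the probability (or indicator) that neighbour *j* is infectious with *k*.
    Isolated nodes get 0.
    """
    q = np.asarray(infectious_marginal, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if q.ndim != 2 or q.shape[0] != net.n or q.shape[1] != beta.shape[0]:
        raise ParameterError(
            f"infectious marginal shape {q.shape} incompatible with n={net.n}, M={beta.shape[0]}"
        )
    a = net.adjacency  # A[j, i] = 1 iff j can transmit to i... (column i = in-neighbours)
    with np.errstate(divide="ignore"):
        log_miss = np.log1p(-beta[None, :] * q)  # log(1 - beta_k q_jk); -inf if certain
    log_prod = a.T @ log_miss  # row i: sum over in-neighbours j
    return -np.expm1(log_prod)


def competitive_suppression(fired, im: InteractionModel) -> float:
    """Joint-adoption survival factor for a set of simultaneously fired
    contagions: ``(1 - a1)`` per competitive pair within the set."""
    supp = 1.0
    fired = list(fired)
    for a, j in enumerate(fired):
        for k in fired[a + 1:]:
            if im.relations[j][k] is Relation.COMPETITIVE:
                supp *= 1.0 - im.a1
    return supp


def _adoption_outcomes(G: np.ndarray, s_coords, im: InteractionModel) -> list:
    """Mass split over adopted-subset outcomes for one source state.

    G is (N, L) with column a the candidate probability of contagion
    ``s_coords[a]``. Returns ``[(digit_offset, weight (N,)), ...]`` covering
    every subset of the S-coordinates; competitive ties are suppressed and
    their mass folded into the empty (no adoption) outcome, so the weights
    sum to 1 exactly.
    """
    n, L = G.shape
    one_minus = 1.0 - G
    outcomes = []
    p_none = np.zeros(n)
    for mask in range(1 << L):
        w = np.ones(n)
        fired = []
        for a in range(L):
            if mask >> a & 1:
                w = w * G[:, a]
                fired.append(s_coords[a])
            else:
                w = w * one_minus[:, a]
        if not fired:
            p_none += w
            continue
        supp = competitive_suppression(fired, im)
        if supp < 1.0:
            p_none += w * (1.0 - supp)
        if supp > 0.0:
            offset = sum(3 ** k for k in fired)  # S (0) -> I (1) per digit
            outcomes.append((offset, w * supp))
    outcomes.append((0, p_none))
    return outcomes


def _recovery_outcomes(i_coords, gamma) -> list:
    """All (state-offset, probability) pairs for independent I -> C flips."""
    out = []
    for flips in itertools.product([0, 1], repeat=len(i_coords)):
        w = 1.0
        offset = 0
        for k, flip in zip(i_coords, flips):
            if flip:
                w *= gamma[k]
                offset += 3 ** k  # I (1) -> C (2) raises digit k by one
            else:
                w *= 1.0 - gamma[k]
        out.append((offset, w))
    return out


def mmca_step(
    dist: JointStateDistribution,
    net: Network,
    rates: RateParams,
    im: InteractionModel,
    mode: str = "consistent",
) -> JointStateDistribution:
    """Advance the joint-state distribution by one synchronous step."""
    if rates.M != im.M or rates.M != dist.M:
        raise ParameterError("rates, interaction model and distribution disagree on M")
    if mode == "verbatim":
        return _verbatim_step(dist, net, rates, im)
    if mode != "consistent":
        raise ParameterError(f"unknown mode {mode!r}")

    M = im.M
    P = dist.P
    f = reception_probabilities(net, dist.infectious_marginal(), rates.beta_array())
    codes = state_table(M)
    mod = modifier_table(im)
    gamma = rates.gamma_array()
    new = np.zeros_like(P)

    for s in range(n_states(M)):
        ps = P[:, s]
        if not ps.any():
            continue
        s_coords = np.flatnonzero(codes[s] == S)
        i_coords = np.flatnonzero(codes[s] == I)
        G = effective_adoption_probability(f[:, s_coords], mod[s, s_coords])
        adoption = _adoption_outcomes(G, list(s_coords), im)
        for r_offset, w_r in _recovery_outcomes(i_coords, gamma):
            if w_r == 0.0:
                continue
            for a_offset, w_a in adoption:
                new[:, s + r_offset + a_offset] += ps * w_a * w_r

    out = JointStateDistribution(new, M)
    err = np.abs(new.sum(axis=1) - 1.0).max()
    if err > 1e-9:
        raise ConsistencyError(f"row sums drifted by {err:.3e} in one step")
    return out


# ---------------------------------------------------------------------------
# Verbatim three-contagion transition table.
#
# Each entry: target label -> list of (source label, factor function). Factor
# functions receive per-node reception probabilities f1, f2, f3 and scalars
# r1, r2, r3, a1, a2. The printed system omits the C1C2C3 self-retention term
# and an equation for I1C2I3; the former is transcribed as printed, the
# latter is synthesised from the uniform adoption rule so the state is not
# silently deleted (see docs/methods.md).
# ---------------------------------------------------------------------------

_VERBATIM_TERMS = {
    "I1S2S3": [
        ("S1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f1 * (1 - f2) * (1 - f3)),
        ("I1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - f2) * (1 - f3)),
    ],
    "S1I2S3": [
        ("S1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f2 * (1 - f1) * (1 - f3)),
        ("S1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2) * (1 - f1) * (1 - f3)),
    ],
    "S1S2I3": [
        ("S1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f3 * (1 - f1) * (1 - f2)),
        ("S1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r3) * (1 - f1) * (1 - f2)),
    ],
    "C1S2S3": [
        ("I1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - f2) * (1 - f3)),
        ("C1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f2) * (1 - f3)),
    ],
    "S1C2S3": [
        ("S1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r2 * (1 - f1) * (1 - f3)),
        ("S1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * (1 - f3)),
    ],
    "S1S2C3": [
        ("S1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r3 * (1 - f1) * (1 - f2)),
        ("S1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * (1 - f2)),
    ],
    "I1I2S3": [
        ("S1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2) * f1 * (1 - f3) * (1 - a1)),
        ("I1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * f2 * (1 - f3) * (1 - a1)),
        ("I1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - r2) * (1 - f3)),
    ],
    "I1S2I3": [
        ("I1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - r3) * (1 - f2)),
        ("S1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r3) * f1 * (1 - f2) * (1 + a2)),
        # printed as f2(1-f3) although the target acquires contagion 3
        ("I1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * f2 * (1 - f3) * (1 + a2)),
    ],
    "S1I2I3": [
        ("S1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * (1 - r2) * (1 - r3)),
        ("S1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r3) * f2 * (1 - f1) * (1 - a1)),
        ("S1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2) * f3 * (1 - f1) * (1 - a1)),
    ],
    "C1I2S3": [
        ("I1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - r2) * (1 - f3)),
        ("C1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f2 * (1 - f3) * (1 - a1)),
        ("C1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2) * (1 - f3)),
    ],
    "I1C2S3": [
        ("I1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * r2 * (1 - f3)),
        ("S1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f1 * (1 - f3) * (1 - a1)),
        ("I1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - f3)),
    ],
    "I1S2C3": [
        ("I1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - f2) * r3),
        # printed without the cooperative (1+a2) boost
        ("S1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f1 * (1 - f2)),
        ("I1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - f2)),
    ],
    "C1S2I3": [
        ("I1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - f2) * (1 - r3)),
        ("C1S2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f2) * f3 * (1 + a2)),
        ("C1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f2) * (1 - r3)),
    ],
    "S1I2C3": [
        ("S1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * (1 - r2)),
        ("S1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * f2 * (1 - a1)),
        ("S1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * (1 - r2) * r3),
    ],
    "S1C2I3": [
        ("S1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * (1 - r3)),
        ("S1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * r2 * (1 - r3)),
        ("S1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * f3 * (1 + a2)),
    ],
    "C1C2S3": [
        ("I1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - f3)),
        ("C1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r2 * (1 - f3)),
        ("C1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f3)),
    ],
    "S1C2C3": [
        ("S1C2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1)),
        ("S1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * r2),
        ("S1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f1) * r3),
    ],
    "C1S2C3": [
        ("I1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - f2)),
        ("C1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f2)),
        ("C1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - f2) * r3),
    ],
    "I1I2I3": [
        ("I1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - r2) * (1 - r3)),
        ("S1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f1 * (1 - r2) * (1 - r3) * (1 - a1) * (1 + a2)),
        ("I1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * f2 * (1 - r3) * (1 - a1) ** 2),
        ("I1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - r2) * f3 * (1 - a1) * (1 + a2)),
    ],
    "I1I2C3": [
        ("S1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f1 * (1 - r2) * (1 - a1) * (1 + a2)),
        ("I1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * f2 * (1 - a1) ** 2),
        ("I1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - r2) * r3),
        ("I1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - r2)),
    ],
    "C1I2I3": [
        ("I1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - r2) * (1 - r3)),
        ("C1S2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f2 * (1 - r3) * (1 - a1) ** 2),
        ("C1I2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2) * f3 * (1 - a1) * (1 + a2)),
        ("C1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2) * (1 - r3)),
    ],
    "C1C2I3": [
        ("I1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - r3)),
        ("C1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r2 * (1 - r3)),
        ("C1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f3 * (1 - a1) * (1 + a2)),
        ("C1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r3)),
    ],
    "C1I2C3": [
        ("I1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1 * (1 - r2)),
        ("C1S2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f2 * (1 - a1) ** 2),
        ("C1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2) * r3),
        ("C1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r2)),
    ],
    "I1C2C3": [
        ("S1C2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f1 * (1 - a1) * (1 + a2)),
        ("I1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * r2),
        ("I1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * r3),
        ("I1C2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1)),
    ],
    "C1C2C3": [
        # self-retention term absent in the printed system (transcribed as is)
        ("I1C2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r1),
        ("C1I2C3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r2),
        ("C1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: r3),
    ],
    # no printed equation exists for I1C2I3; synthesised from the uniform rule
    "I1C2I3": [
        ("I1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * (1 - r3)),
        ("I1I2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * r2 * (1 - r3)),
        ("S1C2I3", lambda f1, f2, f3, r1, r2, r3, a1, a2: f1 * (1 - a1) * (1 + a2) * (1 - r3)),
        ("I1C2S3", lambda f1, f2, f3, r1, r2, r3, a1, a2: (1 - r1) * f3 * (1 - a1) * (1 + a2)),
    ],
}


def _is_canonical_preset(im: InteractionModel) -> bool:
    if im.M != 3:
        return False
    want = [
        [Relation.NEUTRAL, Relation.COMPETITIVE, Relation.COOPERATIVE],
        [Relation.COMPETITIVE, Relation.NEUTRAL, Relation.COMPETITIVE],
        [Relation.COOPERATIVE, Relation.COMPETITIVE, Relation.NEUTRAL],
    ]
    return all(im.relations[j][k] is want[j][k] for j in range(3) for k in range(3))


def _verbatim_step(dist, net, rates, im) -> JointStateDistribution:
    if not _is_canonical_preset(im):
        raise ParameterError(
            "verbatim mode requires M=3 with the canonical relation preset "
            "(contagions 1 and 3 cooperative, contagion 2 competitive with both)"
        )
    P = dist.P
    f = reception_probabilities(net, dist.infectious_marginal(), rates.beta_array())
    f1, f2, f3 = f[:, 0], f[:, 1], f[:, 2]
    r1, r2, r3 = rates.gamma
    new = np.zeros_like(P)
    for target, terms in _VERBATIM_TERMS.items():
        t = parse_state_label(target)
        for source, factor in terms:
            s = parse_state_label(source)
            new[:, t] += P[:, s] * factor(f1, f2, f3, r1, r2, r3, im.a1, im.a2)
    residual = 1.0 - new.sum(axis=1)
    if np.any(residual < -1e-9):
        raise ConsistencyError(
            f"verbatim update produced a negative all-S residual (min {residual.min():.3e}); "
            "the printed system is not mass-conserving at these parameters"
        )
    allS = parse_state_label("S1S2S3")
    new[:, allS] += residual
    return JointStateDistribution(new, 3)


def build_initial_distribution(net: Network, seeds, M: int = None) -> JointStateDistribution:
    """Pure initial condition from per-contagion seed node lists.

    *seeds* is a sequence of node-id lists (or a dict ``{k: list}``). Each
    seeded node starts with probability 1 in the joint state that is I at
    its seeded coordinates and S elsewhere; everyone else is all-S.
    """
    if isinstance(seeds, dict):
        if M is None:
            M = max(seeds) + 1 if seeds else 1
        seed_lists = [list(seeds.get(k, [])) for k in range(M)]
    else:
        seed_lists = [list(s) for s in seeds]
        if M is None:
            M = len(seed_lists)
        elif M != len(seed_lists):
            raise ParameterError(f"got {len(seed_lists)} seed lists for M={M}")
    codes = np.zeros((net.n, M), dtype=np.int64)
    for k, nodes in enumerate(seed_lists):
        for v in nodes:
            if not 0 <= v < net.n:
                raise ParameterError(f"seed node {v} outside 0..{net.n - 1}")
            codes[v, k] = I
    P = np.zeros((net.n, n_states(M)))
    idx = (codes * (3 ** np.arange(M))).sum(axis=1)
    P[np.arange(net.n), idx] = 1.0
    return JointStateDistribution(P, M)


def marginals(dist: JointStateDistribution) -> np.ndarray:
    """(M, 3) network-average S/I/C fraction per contagion."""
    return dist.compartment_marginals().mean(axis=0)


def mmca_run(
    net: Network,
    rates: RateParams,
    im: InteractionModel,
    seeds,
    max_steps: int = 5000,
    tol: float = 1e-9,
    mode: str = "consistent",
) -> Trajectory:
    """Iterate the MMCA recursion to convergence.

    Stops when the largest per-entry change falls below *tol* (the dynamics
    are absorbing, so this coincides with extinction of the I mass) or after
    *max_steps* steps.
    """
    if max_steps < 1:
        raise ParameterError("max_steps must be >= 1")
    dist = build_initial_distribution(net, seeds, M=im.M)
    frames = [marginals(dist)]
    converged = False
    steps = 0
    for steps in range(1, max_steps + 1):
        nxt = mmca_step(dist, net, rates, im, mode=mode)
        delta = np.abs(nxt.P - dist.P).max()
        dist = nxt
        frames.append(marginals(dist))
        if delta < tol:
            converged = True
            break
    fractions = np.stack(frames)
    final = fractions[-1]
    spread = final[:, I] + final[:, C]
    return Trajectory(fractions=fractions, spread_size=spread, steps=steps, converged=converged)
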