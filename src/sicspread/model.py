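"""Parameterisation of the M-contagion SIC model.

Each node carries one compartment per contagion — S (susceptible, never
engaged), I (infected, actively spreading) or C (completed, spread once and
retains the memory but never spreads again). Contagions interact through a
pairwise relation matrix: adopting contagion *k* is penalised by a factor
``(1 - a1)`` for every competing contagion the node already holds or has
completed, and boosted by ``(1 + a2)`` for every cooperating one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import json

import numpy as np

from .network import ParameterError

S, I, C = 0, 1, 2
_COMPARTMENT_NAMES = "SIC"


class Relation(Enum):
    NEUTRAL = "neutral"
    COOPERATIVE = "cooperative"
    COMPETITIVE = "competitive"


@dataclass(frozen=True)
class InteractionModel:
    """M contagions plus their pairwise cooperation/competition structure.

    Parameters
    ----------
    M : int
        Number of contagions (>= 1).
    relations : tuple of tuple of Relation
        Symmetric M x M matrix; the diagonal must be neutral.
    a1 : float
        Inhibiting factor in [0, 1]; each held/completed competitor of a
        contagion multiplies its adoption probability by ``1 - a1``
        (``a1 = 1`` is complete mutual exclusion).
    a2 : float
        Enhancement factor >= 0; each held/completed cooperator multiplies
        the adoption probability by ``1 + a2``.
    """

    M: int
    relations: tuple = field(default=None)
    a1: float = 0.0
    a2: float = 0.0

    def __post_init__(self):
        if self.M < 1:
            raise ParameterError(f"need M >= 1, got {self.M}")
        if not 0.0 <= self.a1 <= 1.0:
            raise ParameterError(f"a1 must lie in [0, 1], got {self.a1}")
        if self.a2 < 0.0:
            raise ParameterError(f"a2 must be >= 0, got {self.a2}")
        rel = self.relations
        if rel is None:
            rel = tuple(tuple(Relation.NEUTRAL for _ in range(self.M)) for _ in range(self.M))
            object.__setattr__(self, "relations", rel)
        rel = tuple(tuple(Relation(r) for r in row) for row in rel)
        object.__setattr__(self, "relations", rel)
        if len(rel) != self.M or any(len(row) != self.M for row in rel):
            raise ParameterError("relations must be an M x M matrix")
        for j in range(self.M):
            if rel[j][j] is not Relation.NEUTRAL:
                raise ParameterError(f"relations[{j}][{j}] must be neutral")
            for k in range(j + 1, self.M):
                if rel[j][k] is not rel[k][j]:
                    raise ParameterError(f"relations must be symmetric; mismatch at ({j}, {k})")

    def pair_factor(self, held: int, candidate: int) -> float:
        """Multiplier on adopting *candidate* given *held* is engaged."""
        r = self.relations[held][candidate]
        if r is Relation.COMPETITIVE:
            return 1.0 - self.a1
        if r is Relation.COOPERATIVE:
            return 1.0 + self.a2
        return 1.0


def three_contagion_preset(a1: float = 0.0, a2: float = 0.0) -> InteractionModel:
    """The canonical three-contagion scenario: contagions 0 and 2 cooperate,
    contagion 1 competes with both."""
    N, P, X = Relation.NEUTRAL, Relation.COOPERATIVE, Relation.COMPETITIVE
    relations = ((N, X, P), (X, N, X), (P, X, N))
    return InteractionModel(M=3, relations=relations, a1=a1, a2=a2)


@dataclass(frozen=True)
class RateParams:
    """Per-contagion infection rates beta and completion rates gamma.

    ``beta[k]`` is the per-edge, per-step probability that an infected
    neighbour transmits contagion *k* to a susceptible node; ``gamma[k]`` is
    the per-step probability an infected node completes (I -> C).
    """

    beta: tuple
    gamma: tuple

    def __post_init__(self):
        beta = tuple(float(b) for b in self.beta)
        gamma = tuple(float(g) for g in self.gamma)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)
        if len(beta) != len(gamma):
            raise ParameterError("beta and gamma must have the same length")
        if not beta:
            raise ParameterError("need at least one contagion")
        for name, vec in (("beta", beta), ("gamma", gamma)):
            if any(not 0.0 <= x <= 1.0 for x in vec):
                raise ParameterError(f"{name} entries must lie in [0, 1], got {vec}")

    @property
    def M(self) -> int:
        return len(self.beta)

    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta)

    def gamma_array(self) -> np.ndarray:
        return np.asarray(self.gamma)


# ---------------------------------------------------------------------------
# Joint-state encoding: index = sum_k code(sigma_k) * 3**k, S=0, I=1, C=2.
# ---------------------------------------------------------------------------

def n_states(M: int) -> int:
    return 3 ** M


def encode_state(labels) -> int:
    """Encode per-contagion compartments (sequence over {0,1,2}) to an index."""
    idx = 0
    for k, lab in enumerate(labels):
        if lab not in (S, I, C):
            raise ParameterError(f"compartment code must be 0 (S), 1 (I) or 2 (C), got {lab}")
        idx += lab * 3 ** k
    return idx


def decode_state(idx: int, M: int) -> tuple:
    labels = []
    for _ in range(M):
        labels.append(idx % 3)
        idx //= 3
    return tuple(labels)


def state_table(M: int) -> np.ndarray:
    """(3^M, M) array of compartment codes, row s = decode_state(s, M)."""
    return np.array([decode_state(s, M) for s in range(n_states(M))], dtype=np.int64)


def state_label(idx: int, M: int) -> str:
    """Human-readable label, e.g. index 7 with M=3 -> 'I1C2S3'."""
    return "".join(f"{_COMPARTMENT_NAMES[c]}{k + 1}" for k, c in enumerate(decode_state(idx, M)))


def parse_state_label(label: str) -> int:
    """Inverse of :func:`state_label` ('C1S2I3' -> index)."""
    codes = {}
    for pos in range(0, len(label), 2):
        comp, k = label[pos], int(label[pos + 1]) - 1
        codes[k] = _COMPARTMENT_NAMES.index(comp)
    return encode_state([codes[k] for k in range(len(codes))])


def adoption_modifier(state, k: int, im: InteractionModel) -> float:
    """Interaction multiplier on node adoption of contagion *k*.

    *state* gives the node's current compartments (sequence of codes or a
    joint-state index). Every other contagion *j* the node has engaged with
    (I or C) contributes ``1 - a1`` if competitive with *k*, ``1 + a2`` if
    cooperative, 1 if neutral; the modifier is the product. Requires the node
    to be susceptible to *k*.
    """
    if isinstance(state, (int, np.integer)):
        state = decode_state(int(state), im.M)
    if state[k] != S:
        raise ParameterError(f"adoption_modifier requires compartment {k} to be S")
    out = 1.0
    for j, lab in enumerate(state):
        if j != k and lab in (I, C):
            out *= im.pair_factor(j, k)
    return out


def modifier_table(im: InteractionModel) -> np.ndarray:
    """(3^M, M) table of adoption modifiers; NaN where the coordinate is not S."""
    table = np.full((n_states(im.M), im.M), np.nan)
    codes = state_table(im.M)
    for s in range(n_states(im.M)):
        for k in range(im.M):
            if codes[s, k] == S:
                table[s, k] = adoption_modifier(tuple(codes[s]), k, im)
    return table


def effective_adoption_probability(f, modifier):
    """Clipped product ``min(1, f * modifier)`` (the enhancement factor is
    unbounded, so the boosted rate must be capped to stay a probability)."""
    return np.minimum(1.0, np.asarray(f, dtype=float) * np.asarray(modifier, dtype=float))


# ---------------------------------------------------------------------------
# Config loading (YAML / JSON)
# ---------------------------------------------------------------------------

def load_config(path) -> tuple:
    """Load ``(InteractionModel, RateParams)`` from a YAML or JSON file.

    Expected keys: ``M``, ``relations`` (matrix of strings), ``a1``, ``a2``,
    ``beta`` (list), ``gamma`` (list). ``relations`` may be omitted for
    all-neutral, or the string ``"three_contagion_preset"``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a mapping, got {type(raw).__name__}")
    missing = {"M", "beta", "gamma"} - raw.keys()
    if missing:
        raise ParameterError(f"config {path} missing keys: {sorted(missing)}")
    m = int(raw["M"])
    a1 = float(raw.get("a1", 0.0))
    a2 = float(raw.get("a2", 0.0))
    relations = raw.get("relations")
    if relations == "three_contagion_preset":
        if m != 3:
            raise ParameterError("three_contagion_preset requires M=3")
        im = three_contagion_preset(a1=a1, a2=a2)
    else:
        if relations is not None:
            try:
                relations = tuple(tuple(Relation(r) for r in row) for row in relations)
            except ValueError as exc:
                raise ParameterError(f"config {path}: {exc}") from None
        im = InteractionModel(M=m, relations=relations, a1=a1, a2=a2)
    rates = RateParams(beta=raw["beta"], gamma=raw["gamma"])
    if rates.M != m:
        raise ParameterError(f"config {path}: beta/gamma length {rates.M} != M={m}")
    return im, rates


def dump_config(im: InteractionModel, rates: RateParams, path) -> None:
    payload = {
        "M": im.M,
        "relations": [[r.value for r in row] for row in im.relations],
        "a1": im.a1,
        "a2": im.a2,
        "beta": list(rates.beta),
        "gamma": list(rates.gamma),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
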