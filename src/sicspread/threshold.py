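"""Spectral stability analysis at the spreading-free equilibrium.

Linearising the MMCA recursion around the all-susceptible state decouples
the contagions: the infectious mode of contagion *k* grows per step by
``(1 - gamma_k) + beta_k * lambda`` with ``lambda`` the spectral radius of
the adjacency matrix, while the mixed and completion modes carry factors
``(1 - gamma_j)(1 - gamma_k)`` and ``(1 - gamma_k)``. The equilibrium is
asymptotically stable — no contagion can invade — iff every magnitude is
below 1, i.e. ``beta_k / gamma_k < 1 / lambda`` for all k. The interaction
factors a1, a2 enter only at second order and do not move the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import RateParams
from .network import Network, ParameterError, spectral_radius


@dataclass(frozen=True)
class ThresholdReport:
    """Spectral threshold summary for one network and rate set."""

    lam: float  # adjacency spectral radius
    eigen_terms: tuple  # Jacobian eigenvalue magnitudes at the zero state
    beta_critical: tuple  # per-contagion critical infection rate gamma_k / lam
    stable: bool  # all eigen magnitudes < 1
    notes: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "eigen_terms": list(self.eigen_terms),
            "beta_critical": [None if math.isinf(b) else b for b in self.beta_critical],
            "stable": self.stable,
            "notes": list(self.notes),
        }


def jacobian_terms(rates: RateParams, lam: float) -> list:
    """Eigenvalue expressions of the linearised update at the zero state.

    Contagion-major order: the M infection terms ``(1 - gamma_k) + beta_k *
    lam``, then the M(M-1)/2 pair terms ``(1 - gamma_j)(1 - gamma_k)`` for
    j < k, then the M completion terms ``(1 - gamma_k)``. For M=3 this is
    the familiar nine-entry list.
    """
    if lam < 0:
        raise ParameterError(f"spectral radius must be >= 0, got {lam}")
    beta = rates.beta
    gamma = rates.gamma
    M = rates.M
    terms = [(1.0 - gamma[k]) + beta[k] * lam for k in range(M)]
    terms += [(1.0 - gamma[j]) * (1.0 - gamma[k]) for j in range(M) for k in range(j + 1, M)]
    terms += [1.0 - gamma[k] for k in range(M)]
    return terms


def stability_report(net: Network, rates: RateParams) -> ThresholdReport:
    """Epidemic-threshold verdict for every contagion on *net*.

    The derivation assumes a symmetric adjacency matrix (Perron–Frobenius),
    so directed networks are refused. A contagion with ``gamma_k = 0`` has no
    finite threshold (an infectious node never completes); it is reported as
    above-threshold with an infinite critical rate and a note.
    """
    if net.directed:
        raise ParameterError("threshold analysis requires an undirected network")
    lam = spectral_radius(net)
    terms = jacobian_terms(rates, lam)
    stable = max(abs(t) for t in terms) < 1.0
    beta_crit = []
    notes = []
    for k, (b, g) in enumerate(zip(rates.beta, rates.gamma)):
        if g == 0.0:
            beta_crit.append(math.inf)
            if b > 0:
                notes.append(
                    f"contagion {k}: gamma=0 leaves the threshold undefined; "
                    "any beta > 0 spreads without completing"
                )
                warnings.warn(notes[-1], stacklevel=2)
        else:
            beta_crit.append(g / lam if lam > 0 else math.inf)
    return ThresholdReport(
        lam=lam,
        eigen_terms=tuple(terms),
        beta_critical=tuple(beta_crit),
        stable=stable,
        notes=tuple(notes),
    )


def numerical_jacobian_radius(
    net: Network,
    rates: RateParams,
    im,
    eps: float = 1e-7,
) -> float:
    """Spectral radius of a finite-difference Jacobian of the consistent-mode
    MMCA update at the zero-infection state, restricted to the per-contagion
    infectious marginals. Used as an independent cross-check of the
    closed-form infection terms."""
    from .mmca import JointStateDistribution, mmca_step
    from .model import I, n_states

    n, M = net.n, im.M
    dim = n * M
    jac = np.empty((dim, dim))
    base = np.zeros((n, n_states(M)))
    base[:, 0] = 1.0

    def step_marginal(q_flat: np.ndarray) -> np.ndarray:
        q = q_flat.reshape(n, M)
        P = base.copy()
        for k in range(M):
            # move q[i, k] of node i's mass from all-S into the I_k state
            P[:, 0] -= q[:, k]
            P[:, 3 ** k] += q[:, k]
        dist = JointStateDistribution(P, M)
        return mmca_step(dist, net, rates, im).infectious_marginal().ravel()

    zero = step_marginal(np.zeros(dim))
    for d in range(dim):
        q = np.zeros(dim)
        q[d] = eps
        jac[:, d] = (step_marginal(q) - zero) / eps
    return float(np.max(np.abs(np.linalg.eigvals(jac))))
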