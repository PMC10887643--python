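"""Config-driven factor sweeps over the interaction parameters.

A sweep varies one of the inhibiting factor ``a1``, the enhancement factor
``a2`` or the attachment parameter ``m`` of the generated scale-free
network, runs the chosen engine (deterministic MMCA or stochastic Monte
Carlo ensemble) at every grid value under a fixed seeding protocol, and
tabulates the final spread size per contagion. Presets mirror the standard
three-contagion scenarios: mutual enhancement (sweep a2), pure competition
(sweep a1 at a2=0), coexistence (a1=1, sweep a2) and the connectivity sweep
over m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .mmca import mmca_run
from .model import InteractionModel, RateParams, three_contagion_preset
from .network import Network, ParameterError, generate_ba
from .simulate import draw_seed_sets, mc_ensemble

#: default sweep grids; figure-scale runs use n=1000 but the desk-scale
#: default keeps the BA network at 300 nodes
DEFAULT_A1_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_A2_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)
DEFAULT_M_GRID = (1, 3, 5)

#: experiment-wide default completion rate (the scenario definitions fix
#: only the infection rates)
DEFAULT_GAMMA = 0.5


@dataclass(frozen=True)
class SweepSpec:
    """Everything needed to reproduce one sweep."""

    engine: str  # "mmca" or "mc"
    rates: RateParams
    im: InteractionModel
    param: str  # swept parameter: "a1", "a2" or "m"
    grid: tuple
    n: int = 300  # BA size when no explicit network is given
    m: int = 3  # BA attachment parameter
    network: Network = None  # explicit network overrides (n, m)
    network_seed: int = 20240209
    seed_count: int = 5
    n_runs: int = 100
    rng_seed: int = 0
    max_steps: int = 2000
    redraw_seeds: bool = True  # mc engine: redraw seed nodes each repetition
    collision_policy: str = "independent"

    def __post_init__(self):
        if self.engine not in ("mmca", "mc"):
            raise ParameterError(f"unknown engine {self.engine!r}")
        if self.param not in ("a1", "a2", "m"):
            raise ParameterError(f"unknown sweep parameter {self.param!r}")
        grid = tuple(self.grid)
        if not grid:
            raise ParameterError("sweep grid must be nonempty")
        if list(grid) != sorted(grid):
            raise ParameterError("sweep grid must be sorted ascending")
        for v in grid:
            if self.param == "a1" and not 0.0 <= v <= 1.0:
                raise ParameterError(f"a1 grid value {v} outside [0, 1]")
            if self.param == "a2" and v < 0.0:
                raise ParameterError(f"a2 grid value {v} must be >= 0")
            if self.param == "m" and (int(v) < 1 or int(v) >= self.n):
                raise ParameterError(f"m grid value {v} must satisfy 1 <= m < n={self.n}")
        object.__setattr__(self, "grid", grid)

    def manifest(self) -> dict:
        return {
            "engine": self.engine,
            "param": self.param,
            "grid": list(self.grid),
            "beta": list(self.rates.beta),
            "gamma": list(self.rates.gamma),
            "a1": self.im.a1,
            "a2": self.im.a2,
            "relations": [[r.value for r in row] for row in self.im.relations],
            "n": self.n,
            "m": self.m,
            "network_seed": self.network_seed,
            "seed_count": self.seed_count,
            "n_runs": self.n_runs,
            "rng_seed": self.rng_seed,
            "max_steps": self.max_steps,
            "redraw_seeds": self.redraw_seeds,
            "collision_policy": self.collision_policy,
            "version": _version,
        }


@dataclass
class SweepResult:
    """One row per (grid value, contagion), plus the reproduction manifest."""

    table: pd.DataFrame  # columns: param, value, contagion, spread_size, se, runs
    manifest: dict = field(default_factory=dict)

    def spread_matrix(self) -> np.ndarray:
        """(len(grid), M) spread sizes in grid order."""
        piv = self.table.pivot(index="value", columns="contagion", values="spread_size")
        return piv.sort_index().to_numpy()


def _with_factor(im: InteractionModel, param: str, value: float) -> InteractionModel:
    kwargs = {"a1": im.a1, "a2": im.a2}
    kwargs[param] = float(value)
    return InteractionModel(M=im.M, relations=im.relations, **kwargs)


def _fixed_seeds(spec: SweepSpec, net: Network):
    """Seed node sets shared by every grid point (comparability along the
    sweep requires the initial condition to stay fixed)."""
    rng = np.random.default_rng(spec.rng_seed)
    return draw_seed_sets(net, spec.seed_count, spec.im.M, rng)


def _run_point(spec: SweepSpec, net: Network, im: InteractionModel, seeds, j: int):
    """Run one engine invocation; returns (spread (M,), se (M,), runs)."""
    if spec.engine == "mmca":
        traj = mmca_run(net, spec.rates, im, seeds, max_steps=spec.max_steps)
        return traj.spread_size, np.zeros(im.M), 1
    # per-grid-point child stream keeps each point reproducible in isolation
    rng = np.random.default_rng([spec.rng_seed, j])
    traj, _ = mc_ensemble(
        net,
        spec.rates,
        im,
        seed_count=spec.seed_count,
        n_runs=spec.n_runs,
        steps=spec.max_steps,
        rng=rng,
        collision_policy=spec.collision_policy,
        seeds=None if spec.redraw_seeds else seeds,
    )
    return traj.spread_size, traj.se, spec.n_runs


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Sweep a1 or a2 on a fixed network (use :func:`run_m_sweep` for m)."""
    if spec.param == "m":
        return run_m_sweep(spec)
    net = spec.network
    if net is None:
        net = generate_ba(spec.n, spec.m, seed=spec.network_seed)
    seeds = _fixed_seeds(spec, net)
    rows = []
    for j, value in enumerate(spec.grid):
        im = _with_factor(spec.im, spec.param, value)
        spread, se, runs = _run_point(spec, net, im, seeds, j)
        for k in range(im.M):
            rows.append(
                {
                    "param": spec.param,
                    "value": value,
                    "contagion": k,
                    "spread_size": spread[k],
                    "se": se[k],
                    "runs": runs,
                }
            )
    return SweepResult(table=pd.DataFrame(rows), manifest=spec.manifest())


def run_m_sweep(spec: SweepSpec) -> SweepResult:
    """Regenerate the BA network for each m value and run the sweep point."""
    if spec.param != "m":
        raise ParameterError("run_m_sweep requires param='m'")
    rows = []
    seeds = None
    for j, m in enumerate(spec.grid):
        net = generate_ba(spec.n, int(m), seed=spec.network_seed)
        if seeds is None:
            seeds = _fixed_seeds(spec, net)  # node count is fixed across m
        spread, se, runs = _run_point(spec, net, spec.im, seeds, j)
        for k in range(spec.im.M):
            rows.append(
                {
                    "param": "m",
                    "value": m,
                    "contagion": k,
                    "spread_size": spread[k],
                    "se": se[k],
                    "runs": runs,
                }
            )
    return SweepResult(table=pd.DataFrame(rows), manifest=spec.manifest())


# ---------------------------------------------------------------------------
# Presets for the standard three-contagion scenarios
# ---------------------------------------------------------------------------

def preset_spec(name: str, engine: str = "mmca", n: int = 300, **overrides) -> SweepSpec:
    """Named sweep presets.

    ``mutual_enhancement``  sweep a2, beta = (0.1, 0.0, 0.1)
    ``asymmetric_enhancement``  sweep a2, beta = (0.1, 0.0, 0.3)
    ``competition``  sweep a1 at a2 = 0, beta = (0.15, 0.3, 0.15)
    ``coexistence``  a1 = 1, sweep a2, beta = (0.15, 0.3, 0.15)
    ``connectivity``  sweep m, beta = (0.1, 0.0, 0.1), fixed a2
    """
    g = DEFAULT_GAMMA
    presets = {
        "mutual_enhancement": dict(
            param="a2",
            grid=DEFAULT_A2_GRID,
            rates=RateParams(beta=(0.1, 0.0, 0.1), gamma=(g, g, g)),
            im=three_contagion_preset(),
        ),
        "asymmetric_enhancement": dict(
            param="a2",
            grid=DEFAULT_A2_GRID,
            rates=RateParams(beta=(0.1, 0.0, 0.3), gamma=(g, g, g)),
            im=three_contagion_preset(),
        ),
        "competition": dict(
            param="a1",
            grid=DEFAULT_A1_GRID,
            rates=RateParams(beta=(0.15, 0.3, 0.15), gamma=(g, g, g)),
            im=three_contagion_preset(a2=0.0),
        ),
        "coexistence": dict(
            param="a2",
            grid=DEFAULT_A2_GRID,
            rates=RateParams(beta=(0.15, 0.3, 0.15), gamma=(g, g, g)),
            im=three_contagion_preset(a1=1.0),
        ),
        "connectivity": dict(
            param="m",
            grid=DEFAULT_M_GRID,
            rates=RateParams(beta=(0.1, 0.0, 0.1), gamma=(g, g, g)),
            im=three_contagion_preset(a2=1.0),
        ),
    }
    if name not in presets:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kwargs = dict(engine=engine, n=n, **presets[name])
    kwargs.update(overrides)
    return SweepSpec(**kwargs)
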