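"""Operator-split coupling of DOM diffusion and decomposition kinetics.

A macro-step advances the whole system by ``max(dt_transform, dt_diffusion)``
seconds: the process with the smaller time step is sub-stepped until both have
advanced the same simulated time, then they alternate.  Only DOM diffuses; the
other four pools are immobile.  The pore space is closed (zero-flux
boundaries), so total carbon is conserved over whole runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .diffusion import DiffusionParams, explicit_step, implicit_step, layer_mass_profile
from .graph import VoxelGraph, laplacian
from .kinetics import (
    POOLS,
    BioParams,
    PoreState,
    transform_step_asynchronous,
    transform_step_synchronous,
)
from .units import SECONDS_PER_DAY

__all__ = [
    "ScenarioConfig",
    "SimulationRecord",
    "initialize_scenario",
    "run_coupled",
    "compound_fractions",
]


@dataclass
class ScenarioConfig:
    """Configuration of a decomposition scenario.

    Masses are abstract carbon masses (µg C by convention); the dynamics are
    invariant to their overall scale except through the Monod half-saturation.
    Defaults mirror the reference decomposition experiment: 289.5 µg DOM
    spread uniformly over the pore space, 1000 bacterial spots totalling
    5.2e7 cells at 5.41e-8 µg C per cell.
    """

    d: float = 100950.0              # DOM diffusion coefficient, voxel^2/day
    dom_total: float = 289.5         # µg C
    dom_placement: str = "uniform"   # "uniform" | "first_two_z_layers"
    n_spots: int = 1000
    mb_total: Optional[float] = None  # µg C; overrides the cell count if set
    n_cells: float = 5.2e7
    carbon_per_cell: float = 5.41e-8  # µg C per bacterial cell
    som_total: float = 0.0
    fom_total: float = 0.0
    dt_diffusion: float = 600.0      # seconds
    dt_transform: float = 600.0      # seconds
    scheme: str = "implicit"         # diffusion scheme
    transform_mode: str = "asynchronous"
    splitting: str = "transform_first"  # or "diffusion_first"
    duration: float = 5 * SECONDS_PER_DAY  # seconds
    output_every: float = 3600.0     # seconds
    record_profiles: bool = False
    profile_axis: str = "z"
    seed: int = 0
    pcg_tol: float = 1e-12

    def mb_mass(self) -> float:
        if self.mb_total is not None:
            return self.mb_total
        return self.n_cells * self.carbon_per_cell

    def validate(self) -> None:
        if self.dt_diffusion <= 0 or self.dt_transform <= 0:
            raise ValueError("time steps must be positive")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.scheme not in ("explicit", "implicit"):
            raise ValueError(f"unknown diffusion scheme {self.scheme!r}")
        if self.transform_mode not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown transform mode {self.transform_mode!r}")
        if self.splitting not in ("transform_first", "diffusion_first"):
            raise ValueError(f"unknown splitting order {self.splitting!r}")
        macro = max(self.dt_diffusion, self.dt_transform)
        for name, dt in (("dt_diffusion", self.dt_diffusion), ("dt_transform", self.dt_transform)):
            if not _divides(dt, macro):
                raise ValueError(f"{name}={dt} must divide the macro step {macro}")
            if not _divides(dt, self.output_every):
                raise ValueError(f"{name}={dt} must divide output_every={self.output_every}")
        if not _divides(macro, self.output_every):
            raise ValueError("the macro step must divide the output cadence")


@dataclass
class SimulationRecord:
    """Recorded time series of a coupled run."""

    times: np.ndarray                      # seconds
    totals: np.ndarray                     # (n_times, 5), columns ordered as POOLS
    profiles: Optional[np.ndarray] = None  # (n_times, extent) DOM layer profiles
    final_state: Optional[PoreState] = None

    def totals_dict(self) -> dict[str, np.ndarray]:
        return {pool: self.totals[:, k] for k, pool in enumerate(POOLS)}


def _divides(small: float, big: float, rtol: float = 1e-9) -> bool:
    if small <= 0:
        return False
    ratio = big / small
    return abs(ratio - round(ratio)) <= rtol * max(1.0, ratio)


def _steps(small: float, big: float) -> int:
    return int(round(big / small))


def initialize_scenario(cfg: ScenarioConfig, graph: VoxelGraph) -> PoreState:
    """Place the initial DOM, biomass, SOM and FOM on the pore graph.

    DOM is split equally over the selected pore voxels; biomass is placed as
    ``n_spots`` equal point masses at distinct pore voxels drawn with the
    scenario seed.  SOM/FOM totals (if any) are spread uniformly.
    """
    cfg.validate()
    n = graph.n
    if n == 0:
        raise ValueError("cannot initialize a scenario on an empty pore graph")
    state = PoreState.zeros(n)

    if cfg.dom_placement == "uniform":
        sel = np.arange(n)
    elif cfg.dom_placement == "first_two_z_layers":
        sel = np.flatnonzero(graph.node_coords[:, 2] <= 1)
        if sel.size == 0:
            raise ValueError("no pore voxels in the first two z layers")
    else:
        raise ValueError(f"unknown dom_placement {cfg.dom_placement!r}")
    state.dom[sel] = cfg.dom_total / sel.size

    if cfg.n_spots > 0:
        if cfg.n_spots > n:
            raise ValueError(f"{cfg.n_spots} bacterial spots requested but only {n} pore voxels")
        rng = np.random.default_rng(cfg.seed)
        spots = rng.choice(n, size=cfg.n_spots, replace=False)
        state.mb[spots] += cfg.mb_mass() / cfg.n_spots

    if cfg.som_total:
        state.som += cfg.som_total / n
    if cfg.fom_total:
        state.fom += cfg.fom_total / n
    return state


def run_coupled(
    state0: PoreState,
    graph: VoxelGraph,
    bio: BioParams,
    cfg: ScenarioConfig,
    lap: Optional[sp.spmatrix] = None,
) -> SimulationRecord:
    """Run the operator-split transformation/diffusion simulation.

    Within each macro-step the configured ``splitting`` order is honored and
    the smaller-dt process is sub-stepped so both processes advance the same
    elapsed time.  Solver errors propagate annotated with the simulated time.
    """
    cfg.validate()
    if lap is None:
        lap = laplacian(graph)
    dparams = DiffusionParams(d=cfg.d, dt=cfg.dt_diffusion)
    dt_trans_days = cfg.dt_transform / SECONDS_PER_DAY
    transform = (
        transform_step_synchronous
        if cfg.transform_mode == "synchronous"
        else transform_step_asynchronous
    )

    macro = max(cfg.dt_diffusion, cfg.dt_transform)
    n_trans = _steps(cfg.dt_transform, macro)
    n_diff = _steps(cfg.dt_diffusion, macro)
    n_out = int(round(cfg.duration / cfg.output_every)) if cfg.duration > 0 else 0
    macros_per_out = _steps(macro, cfg.output_every)

    state = state0.copy()
    times = [0.0]
    totals = [state.pool_totals()]
    profiles = [layer_mass_profile(state.dom, graph, cfg.profile_axis)] if cfg.record_profiles else None

    t = 0.0
    for _ in range(n_out):
        for _ in range(macros_per_out):
            try:
                if cfg.splitting == "transform_first":
                    state = _transform_block(state, bio, dt_trans_days, n_trans, transform)
                    state.dom = _diffuse_block(state.dom, lap, dparams, n_diff, cfg)
                else:
                    state.dom = _diffuse_block(state.dom, lap, dparams, n_diff, cfg)
                    state = _transform_block(state, bio, dt_trans_days, n_trans, transform)
            except RuntimeError as err:
                err.args = (f"at simulated time {t:.6g} s: {err}",)
                raise
            t += macro
        times.append(t)
        totals.append(state.pool_totals())
        if profiles is not None:
            profiles.append(layer_mass_profile(state.dom, graph, cfg.profile_axis))

    return SimulationRecord(
        times=np.asarray(times),
        totals=np.asarray(totals),
        profiles=None if profiles is None else np.asarray(profiles),
        final_state=state,
    )


def _transform_block(state, bio, dt_days, n_steps, transform):
    for _ in range(n_steps):
        state = transform(state, bio, dt_days)
    return state


def _diffuse_block(dom, lap, dparams, n_steps, cfg):
    for _ in range(n_steps):
        if cfg.scheme == "explicit":
            dom = explicit_step(dom, lap, dparams)
        else:
            dom = implicit_step(dom, lap, dparams, tol=cfg.pcg_tol)
    return dom


def compound_fractions(state: PoreState) -> dict[str, float]:
    """Share of total carbon held by each pool; shares sum to 1."""
    totals = state.pool_totals()
    total = totals.sum()
    if total <= 0:
        raise ValueError("compound fractions are undefined for zero total carbon")
    return {pool: float(totals[k] / total) for k, pool in enumerate(POOLS)}
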