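"""Five-pool microbial decomposition kinetics.

Each pore voxel carries five carbon pools: microbial biomass (MB), dissolved
organic matter (DOM), soil organic matter (SOM), fresh organic matter (FOM)
and respired CO2.  Within a voxel the pools evolve by

* growth: Monod uptake DOM -> MB at rate ``v_dom * dom/(k_dom + dom) * mb``,
* mortality: MB -> DOM (fraction ``beta``) and SOM (fraction ``1 - beta``)
  at rate ``mu * mb``,
* respiration: MB -> CO2 at rate ``rho * mb``,
* hydrolysis: SOM -> DOM at rate ``v_som * som`` and FOM -> DOM at rate
  ``v_fom * fom``.

Every process moves carbon between pools, so each step conserves total carbon
exactly in the rate algebra.  Rates are configured in day^-1 (the unit the
soil literature reports); the time step passed to the steppers is therefore
in days.  The coupled simulator converts its second-based clock centrally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "POOLS",
    "BioParams",
    "PoreState",
    "NegativePoolError",
    "monod_uptake",
    "transform_step_synchronous",
    "transform_step_asynchronous",
    "closed_form_fom",
    "stable_transform_dt",
]

POOLS = ("mb", "dom", "som", "fom", "co2")


class NegativePoolError(RuntimeError):
    """A pool went negative during a transformation step (dt too large)."""


@dataclass(frozen=True)
class BioParams:
    """Biological rate parameters (day^-1 except where noted).

    Defaults are the Arthrobacter sp. 9R set calibrated on experimental growth
    and respiration curves: respiration 0.2/d, mortality 0.5/d, 55% of dead
    biomass recycled to DOM, SOM and FOM hydrolysis 0.01/d and 0.3/d, maximum
    growth 9.6/d with DOM half-saturation 0.001 (same mass unit as the pools).
    """

    rho: float = 0.2     # respiration rate, day^-1
    mu: float = 0.5      # mortality rate, day^-1
    beta: float = 0.55   # fraction of dead MB recycled to DOM (rest to SOM)
    v_dom: float = 9.6   # max MB growth rate, day^-1
    k_dom: float = 0.001  # DOM half-saturation, pool mass units
    v_som: float = 0.01  # SOM hydrolysis rate, day^-1
    v_fom: float = 0.3   # FOM hydrolysis rate, day^-1

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "v_dom", "k_dom", "v_som", "v_fom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


#: The default parameter set (Arthrobacter sp. 9R).
ARTHROBACTER = BioParams()


@dataclass
class PoreState:
    """Per-node masses of the five carbon pools (same unit each, e.g. µg C)."""

    mb: np.ndarray
    dom: np.ndarray
    som: np.ndarray
    fom: np.ndarray
    co2: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, p), dtype=np.float64) for p in POOLS]
        n = arrays[0].shape
        for p, a in zip(POOLS, arrays):
            if a.shape != n:
                raise ValueError("all pools must have the same length")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"pool {p} contains non-finite values")
            setattr(self, p, a)

    @classmethod
    def zeros(cls, n: int) -> "PoreState":
        return cls(*(np.zeros(n) for _ in POOLS))

    @property
    def n(self) -> int:
        return self.mb.size

    def copy(self) -> "PoreState":
        return PoreState(*(getattr(self, p).copy() for p in POOLS))

    def pool_totals(self) -> np.ndarray:
        """Totals over nodes, ordered as POOLS."""
        return np.array([getattr(self, p).sum() for p in POOLS])

    def total_carbon(self) -> float:
        return float(self.pool_totals().sum())

    def min_pool(self) -> float:
        return min(float(getattr(self, p).min(initial=0.0)) for p in POOLS)


def monod_uptake(mb, dom, p: BioParams, dt: float):
    """DOM mass taken up by biomass over ``dt`` days, capped at available DOM.

    The cap keeps the finite-dt update nonnegative; it is inactive whenever
    ``v_dom * dt < 1`` since uptake <= v_dom*mb*dt * dom/(k_dom+dom).
    """
    mb = np.asarray(mb, dtype=np.float64)
    dom = np.asarray(dom, dtype=np.float64)
    denom = p.k_dom + dom
    frac = np.divide(dom, denom, out=np.zeros_like(dom + mb), where=denom > 0)
    return np.minimum(p.v_dom * frac * mb * dt, dom)


def _check_nonnegative(state: PoreState) -> None:
    for pool in POOLS:
        vals = getattr(state, pool)
        if vals.size and vals.min() < 0:
            node = int(np.argmin(vals))
            raise NegativePoolError(
                f"pool {pool!r} at node {node} went negative "
                f"({vals[node]:.3e}); reduce the transformation dt"
            )


def transform_step_synchronous(state: PoreState, p: BioParams, dt: float) -> PoreState:
    """One explicit transformation step, all pools read at time t.

    ``dt`` is in days.  Total carbon per node is conserved exactly in the rate
    algebra (mortality splits beta/(1-beta) between DOM and SOM, respiration
    moves MB to CO2, hydrolysis moves SOM/FOM to DOM).
    """
    uptake = monod_uptake(state.mb, state.dom, p, dt)
    mortality = p.mu * state.mb * dt
    respiration = p.rho * state.mb * dt
    hyd_som = p.v_som * state.som * dt
    hyd_fom = p.v_fom * state.fom * dt

    out = PoreState(
        mb=state.mb + uptake - mortality - respiration,
        dom=state.dom - uptake + p.beta * mortality + hyd_som + hyd_fom,
        som=state.som + (1.0 - p.beta) * mortality - hyd_som,
        fom=state.fom - hyd_fom,
        co2=state.co2 + respiration,
    )
    _check_nonnegative(out)
    return out


def transform_step_asynchronous(state: PoreState, p: BioParams, dt: float) -> PoreState:
    """One transformation step applied as sequential process sweeps.

    Fixed order, each process reading the state left by the previous one:
    (1) growth, (2) mortality, (3) respiration, (4) hydrolysis.  Differs from
    the synchronous update by O(dt^2); conserves carbon exactly the same way.
    """
    out = state.copy()
    # 1. growth
    uptake = monod_uptake(out.mb, out.dom, p, dt)
    out.mb += uptake
    out.dom -= uptake
    # 2. mortality
    mortality = p.mu * out.mb * dt
    out.mb -= mortality
    out.dom += p.beta * mortality
    out.som += (1.0 - p.beta) * mortality
    # 3. respiration
    respiration = p.rho * out.mb * dt
    out.mb -= respiration
    out.co2 += respiration
    # 4. hydrolysis
    hyd_som = p.v_som * out.som * dt
    hyd_fom = p.v_fom * out.fom * dt
    out.som -= hyd_som
    out.fom -= hyd_fom
    out.dom += hyd_som + hyd_fom
    _check_nonnegative(out)
    return out


def closed_form_fom(f0: float, v_fom: float, t: float) -> float:
    """Exact FOM decay ``f0 * exp(-v_fom * t)`` (t in days); test oracle."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return f0 * float(np.exp(-v_fom * t))


def stable_transform_dt(p: BioParams) -> float:
    """A dt (days) below which no pool can go negative in one step.

    MB is the binding pool: its relative loss per step is at most
    ``(rho + mu) * dt`` in the synchronous update (growth only adds), and
    uptake is capped at the available DOM, so
    ``dt <= 1 / (rho + mu + v_dom)`` is sufficient for every pool.
    """
    denom = p.rho + p.mu + p.v_dom
    return np.inf if denom == 0 else 1.0 / denom
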