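"""Graph diffusion equation solvers.

The diffusion of dissolved organic matter over the pore graph obeys
``dM/dt = -D * L @ M`` where ``L`` is the graph Laplacian.  Two time
discretizations are provided:

* explicit (forward Euler):  ``M' = M - D*dt * L @ M``
* implicit (backward Euler): ``(I + D*dt * L) @ M' = M``, solved with a
  Jacobi-preconditioned conjugate gradient.

Both conserve total mass exactly (up to the linear-solver residual for the
implicit scheme) because the Laplacian's rows sum to zero.  The diffusion
coefficient ``D`` is configured in voxel^2/day and time steps in seconds; the
conversion is centralized in :mod:`poregraph.units`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from .graph import VoxelGraph
from .units import SECONDS_PER_DAY, coupling

__all__ = [
    "DiffusionParams",
    "StabilityError",
    "ConvergenceError",
    "explicit_step",
    "implicit_step",
    "pcg_solve",
    "stable_timestep",
    "stable_timestep_seconds",
    "simulate_diffusion",
    "layer_mass_profile",
    "intercorrelation",
]

#: Default relative-residual tolerance for the PCG solver.  Tight, so that the
#: implicit scheme's mass-conservation defect stays near machine precision.
DEFAULT_PCG_TOL = 1e-10


class StabilityError(RuntimeError):
    """Explicit step produced negative masses (time step too large)."""


class ConvergenceError(RuntimeError):
    """Iterative solver failed to reach tolerance; carries residual history."""

    def __init__(self, message: str, residuals: Sequence[float]):
        super().__init__(message)
        self.residuals = list(residuals)


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion coefficient and time step.

    Parameters
    ----------
    d
        Diffusion coefficient in voxel^2/day (e.g. 100950 for dissolved
        organic matter in water at 24 µm voxels).
    dt
        Time step in seconds.
    """

    d: float
    dt: float

    def __post_init__(self) -> None:
        if self.d < 0 or self.dt <= 0:
            raise ValueError("D must be >= 0 and dt > 0")

    @property
    def theta(self) -> float:
        """Dimensionless step coupling D*dt (voxel^2)."""
        return coupling(self.d, self.dt)


# Negative values smaller than this (relative to the state scale) are treated
# as rounding noise, not instability.
_NEG_TOL = 1e-12


def explicit_step(m: np.ndarray, lap: sp.spmatrix, p: DiffusionParams) -> np.ndarray:
    """One forward-Euler step ``M' = M - D*dt * L @ M``.

    Raises :class:`StabilityError` if the step drives any mass negative, which
    happens iff ``D*dt`` exceeds the bound of :func:`stable_timestep`.
    """
    m = np.asarray(m, dtype=np.float64)
    out = m - p.theta * (lap @ m)
    scale = float(np.max(np.abs(m), initial=0.0))
    if out.size and out.min() < -_NEG_TOL * max(scale, 1.0):
        deg_max = int(lap.diagonal().max())
        bound = SECONDS_PER_DAY / (p.d * deg_max)
        raise StabilityError(
            f"explicit step with dt={p.dt} s produced negative mass "
            f"{out.min():.3e}; stable bound is dt <= {bound:.6g} s "
            f"(1/(D*deg_max) with deg_max={deg_max})"
        )
    return out


def pcg_solve(
    apply_a: Callable[[np.ndarray], np.ndarray] | sp.spmatrix | np.ndarray,
    b: np.ndarray,
    precond_diag: np.ndarray,
    tol: float = DEFAULT_PCG_TOL,
    maxiter: int | None = None,
) -> np.ndarray:
    """Jacobi-preconditioned conjugate gradient for SPD systems.

    Parameters
    ----------
    apply_a
        The SPD operator, as a matrix or a callable ``x -> A @ x``.
    b
        Right-hand side.
    precond_diag
        Diagonal of the preconditioner, i.e. ``1 / diag(A)``.
    tol
        Convergence criterion on the relative residual ``||A x - b|| / ||b||``.
    maxiter
        Iteration cap; defaults to ``max(1000, len(b))``.
    """
    matvec = apply_a if callable(apply_a) else (lambda x: apply_a @ x)
    b = np.asarray(b, dtype=np.float64)
    n = b.size
    if maxiter is None:
        maxiter = max(1000, n)
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return np.zeros_like(b)

    x = np.zeros_like(b)
    r = b.copy()
    z = precond_diag * r
    p = z.copy()
    rz = float(r @ z)
    residuals: list[float] = [1.0]
    for _ in range(maxiter):
        ap = matvec(p)
        alpha = rz / float(p @ ap)
        x += alpha * p
        r -= alpha * ap
        res = float(np.linalg.norm(r)) / bnorm
        residuals.append(res)
        if res <= tol:
            return x
        z = precond_diag * r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise ConvergenceError(
        f"PCG did not reach tol={tol} within {maxiter} iterations "
        f"(final relative residual {residuals[-1]:.3e})",
        residuals,
    )


def implicit_step(
    m: np.ndarray,
    lap: sp.spmatrix,
    p: DiffusionParams,
    tol: float = DEFAULT_PCG_TOL,
    maxiter: int | None = None,
) -> np.ndarray:
    """One backward-Euler step: solve ``(I + D*dt*L) M' = M`` by PCG.

    The system matrix is a symmetric M-matrix, so the solution is nonnegative
    for nonnegative input and unconditionally stable in dt.
    """
    m = np.asarray(m, dtype=np.float64)
    a = p.theta
    b_mat = sp.identity(m.size, format="csr") + a * lap.tocsr()
    diag = 1.0 + a * lap.diagonal()
    return pcg_solve(b_mat, m, 1.0 / diag, tol=tol, maxiter=maxiter)


def stable_timestep(graph: VoxelGraph, d: float) -> float:
    """Largest explicit time step guaranteeing nonnegativity, ``1/(D*deg_max)``.

    Unit-agnostic: the result carries the inverse time unit of ``d`` (a D in
    voxel^2/s gives dt in seconds).  Raises on an empty graph.
    """
    if graph.n == 0:
        raise ValueError("stable_timestep is undefined on an empty graph")
    if d <= 0:
        raise ValueError("D must be positive")
    deg_max = int(graph.degrees.max())
    if deg_max == 0:
        return np.inf
    return 1.0 / (d * deg_max)


def stable_timestep_seconds(graph: VoxelGraph, d_voxel2_per_day: float) -> float:
    """Explicit stability bound in seconds for a D given in voxel^2/day."""
    return stable_timestep(graph, d_voxel2_per_day / SECONDS_PER_DAY)


def simulate_diffusion(
    m0: np.ndarray,
    lap: sp.spmatrix,
    p: DiffusionParams,
    n_steps: int,
    scheme: str = "implicit",
    record_every: int | None = None,
    tol: float = DEFAULT_PCG_TOL,
    maxiter: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``n_steps`` diffusion steps, recording every ``record_every`` steps.

    Returns ``(times, states)`` where ``times`` are in seconds (0 included)
    and ``states`` has one recorded mass vector per row.  ``record_every=None``
    records only the initial and final states.
    """
    if scheme not in ("explicit", "implicit"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    m = np.asarray(m0, dtype=np.float64).copy()
    cadence = record_every if record_every is not None else max(n_steps, 1)
    times = [0.0]
    states = [m.copy()]
    for k in range(1, n_steps + 1):
        if scheme == "explicit":
            m = explicit_step(m, lap, p)
        else:
            m = implicit_step(m, lap, p, tol=tol, maxiter=maxiter)
        if k % cadence == 0 or k == n_steps:
            times.append(k * p.dt)
            states.append(m.copy())
    return np.asarray(times), np.asarray(states)


_AXES = {"x": 0, "y": 1, "z": 2}


def layer_mass_profile(m: np.ndarray, graph: VoxelGraph, axis: str = "z") -> np.ndarray:
    """Total mass per layer along an axis; sums to the total mass."""
    try:
        ax = _AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}") from None
    extent = graph.shape[ax]
    return np.bincount(graph.node_coords[:, ax], weights=np.asarray(m, float), minlength=extent)


def intercorrelation(c1: np.ndarray, c2: np.ndarray) -> float:
    """Cosine similarity between two layer-profile curves, in [-1, 1]."""
    c1 = np.asarray(c1, dtype=np.float64)
    c2 = np.asarray(c2, dtype=np.float64)
    if c1.shape != c2.shape:
        raise ValueError("profiles must have equal length")
    n1 = np.linalg.norm(c1)
    n2 = np.linalg.norm(c2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("intercorrelation is undefined for a zero-norm curve")
    return float(c1 @ c2 / (n1 * n2))
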