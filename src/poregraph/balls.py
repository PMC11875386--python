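"""Ball-network (pore network geometrical model) representation of pore space.

The pore space is approximated by a set of overlapping balls.  Two balls are
adjacent iff they strictly overlap; each edge carries a contact surface S_ij
(the area of the sphere-sphere intersection disc), a center distance d_ij and
a diffusional conductance theta_ij, classically initialized to S_ij / d_ij.
Fickian mass exchange between adjacent balls is scaled per edge by theta_ij
and driven by the concentration difference m_i/v_i - m_j/v_j.

Voxel <-> ball mappings let ball-scale simulations be compared against (and
learned from) voxel-graph simulations of the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from .diffusion import StabilityError, pcg_solve
from .graph import VoxelGraph
from .image import BinaryImage3D, PORE, SOLID
from .units import coupling

__all__ = [
    "Ball",
    "BallNetwork",
    "build_ball_network",
    "voxelize_balls",
    "map_voxels_to_balls",
    "partition_volumes",
    "ball_masses_from_voxels",
    "uniform_voxel_masses_from_balls",
    "pngm_explicit_step",
    "pngm_implicit_step",
]


@dataclass(frozen=True)
class Ball:
    """A spherical primitive: continuous center (voxel units) and radius."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ball radius must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def volume(self) -> float:
        """Analytic volume (4/3) pi r^3 in voxel^3."""
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class BallNetwork:
    """Adjacency network over a ball set with per-edge conductances.

    ``edges`` holds each unordered adjacent pair once (i < j); ``theta`` is
    symmetric by construction (one value per undirected edge).
    """

    balls: list[Ball]
    edges: np.ndarray             # (m, 2) int
    contact_surface: np.ndarray   # (m,) voxel^2
    center_distance: np.ndarray   # (m,) voxel
    theta: np.ndarray             # (m,) conductances, >= 0
    volumes: np.ndarray = None    # (q,) ball volumes; analytic by default

    def __post_init__(self) -> None:
        if self.volumes is None:
            self.volumes = np.array([b.volume for b in self.balls])

    @property
    def q(self) -> int:
        return len(self.balls)

    @property
    def analytic_volumes(self) -> np.ndarray:
        return np.array([b.volume for b in self.balls])

    def with_volumes(self, volumes: np.ndarray) -> "BallNetwork":
        """Copy of the network with ball volumes replaced.

        Used to swap in partition-cell volumes (covered-voxel counts), which
        make ball concentrations consistent with the voxel<->ball mass maps:
        the network's equilibrium then coincides with the aggregated voxel
        equilibrium of the same geometry.
        """
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.shape != (self.q,) or volumes.min() <= 0:
            raise ValueError("need one positive volume per ball")
        return replace(self, volumes=volumes.copy())

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.balls])

    def with_theta(self, theta: np.ndarray) -> "BallNetwork":
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != self.theta.shape:
            raise ValueError("theta must have one entry per edge")
        if theta.size and theta.min() < 0:
            raise ValueError("conductances must be nonnegative")
        return replace(self, theta=theta.copy())

    def theta_laplacian(self, theta: Optional[np.ndarray] = None) -> sp.csr_matrix:
        """Weighted Laplacian L with L[i,i] = sum_j theta_ij, L[i,j] = -theta_ij."""
        th = self.theta if theta is None else np.asarray(theta, dtype=np.float64)
        q = self.q
        if self.edges.size == 0:
            return sp.csr_matrix((q, q))
        i, j = self.edges.T
        w = sp.csr_matrix(
            (np.concatenate([th, th]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(q, q),
        )
        deg = np.asarray(w.sum(axis=1)).ravel()
        return (sp.diags(deg) - w).tocsr()


def _intersection_disc_area(r1: float, r2: float, d: float) -> float:
    """Area of the circle where two overlapping spheres intersect.

    If one ball is fully inside the other there is no intersection circle; the
    contact surface is then taken as the full cross-section of the smaller
    ball (the throat cannot be wider than the smaller ball).
    """
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    x = (d * d - r2 * r2 + r1 * r1) / (2.0 * d)  # distance from center 1 to the plane
    rc2 = r1 * r1 - x * x
    return np.pi * max(rc2, 0.0)


def build_ball_network(
    balls: Sequence[Ball],
    contact: str = "analytic",
    image: Optional[BinaryImage3D] = None,
    graph: Optional[VoxelGraph] = None,
) -> BallNetwork:
    """Construct the adjacency network of a ball set.

    Edges join balls whose centers are strictly closer than the sum of their
    radii (tangent balls are not adjacent).  ``contact="analytic"`` uses the
    sphere-sphere intersection disc area for S_ij; ``contact="voxel"`` counts
    shared boundary faces between the voxel partition cells of the two balls
    (requires ``image`` and ``graph`` of the voxelized ball set).  Conductances
    are initialized to S_ij / d_ij.
    """
    balls = list(balls)
    if not balls:
        raise ValueError("need at least one ball")
    centers = np.array([b.center for b in balls])
    radii = np.array([b.radius for b in balls])
    q = len(balls)
    if q > 1:
        dmat = squareform(pdist(centers))
    else:
        dmat = np.zeros((1, 1))
    ii, jj = np.triu_indices(q, k=1)
    if np.any(dmat[ii, jj] == 0.0):
        k = int(np.argmax(dmat[ii, jj] == 0.0))
        raise ValueError(f"balls {ii[k]} and {jj[k]} have coincident centers")
    overlap = dmat[ii, jj] < radii[ii] + radii[jj]
    edges = np.column_stack([ii[overlap], jj[overlap]]).astype(np.int64)
    dist = dmat[edges[:, 0], edges[:, 1]] if len(edges) else np.empty(0)

    if contact == "analytic":
        surf = np.array(
            [
                _intersection_disc_area(radii[i], radii[j], d)
                for (i, j), d in zip(edges, dist)
            ]
        )
    elif contact == "voxel":
        if image is None or graph is None:
            raise ValueError("contact='voxel' requires the voxelized image and its graph")
        labels = map_voxels_to_balls(graph, balls)
        surf = _voxel_contact_surfaces(graph, labels, edges)
    else:
        raise ValueError(f"unknown contact mode {contact!r}")

    theta = np.divide(surf, dist, out=np.zeros_like(surf), where=dist > 0)
    return BallNetwork(
        balls=balls,
        edges=edges,
        contact_surface=surf,
        center_distance=dist,
        theta=theta,
    )


def _voxel_contact_surfaces(graph: VoxelGraph, labels: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Count voxel faces shared between the partition cells of each ball pair."""
    la = labels[graph.edges[:, 0]]
    lb = labels[graph.edges[:, 1]]
    cross = la != lb
    lo = np.minimum(la[cross], lb[cross])
    hi = np.maximum(la[cross], lb[cross])
    counts: dict[tuple[int, int], int] = {}
    for a, b in zip(lo.tolist(), hi.tolist()):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return np.array([float(counts.get((int(i), int(j)), 0)) for i, j in edges])


def _voxel_centers(dims: tuple[int, int, int]):
    xs = np.arange(dims[0]) + 0.5
    ys = np.arange(dims[1]) + 0.5
    zs = np.arange(dims[2]) + 0.5
    return xs, ys, zs


def voxelize_balls(balls: Sequence[Ball], dims: tuple[int, int, int]) -> BinaryImage3D:
    """Binary image with a pore voxel wherever the voxel center lies in a ball.

    Voxel ``(i, j, k)`` has its center at ``(i+0.5, j+0.5, k+0.5)`` in the
    continuous coordinates of the ball centers.
    """
    vals = np.full(dims, SOLID, dtype=np.uint8)
    xs, ys, zs = _voxel_centers(dims)
    for b in balls:
        cx, cy, cz = b.center
        r = b.radius
        sl = tuple(
            slice(max(0, int(np.floor(c - r - 1))), min(n, int(np.ceil(c + r + 1))))
            for c, n in zip(b.center, dims)
        )
        dx = xs[sl[0]] - cx
        dy = ys[sl[1]] - cy
        dz = zs[sl[2]] - cz
        d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        vals[sl][d2 <= r * r] = PORE
    return BinaryImage3D(vals)


def map_voxels_to_balls(graph: VoxelGraph, balls: Sequence[Ball]) -> np.ndarray:
    """Partition pore voxels among covering balls.

    Each voxel goes to the nearest-center ball containing it; ties go to the
    lowest ball index (balls are scanned in index order with a strict-improve
    rule).  Raises if any pore voxel is covered by no ball.
    """
    pts = graph.node_coords + 0.5
    n = graph.n
    best_d2 = np.full(n, np.inf)
    labels = np.full(n, -1, dtype=np.int64)
    for k, b in enumerate(balls):
        d2 = np.sum((pts - np.asarray(b.center)) ** 2, axis=1)
        inside = d2 <= b.radius**2
        better = inside & (d2 < best_d2)
        labels[better] = k
        best_d2[better] = d2[better]
    if np.any(labels < 0):
        missing = graph.node_coords[labels < 0][:5]
        raise ValueError(
            f"{int((labels < 0).sum())} pore voxels are covered by no ball, "
            f"e.g. at coordinates {missing.tolist()}"
        )
    return labels


def partition_volumes(labels: np.ndarray, q: int) -> np.ndarray:
    """Covered-voxel count per ball (the partition-cell volume, voxel^3)."""
    return np.bincount(labels, minlength=q).astype(np.float64)


def ball_masses_from_voxels(m: np.ndarray, labels: np.ndarray, q: int) -> np.ndarray:
    """Aggregate voxel masses to per-ball masses (sums within partition cells)."""
    return np.bincount(labels, weights=np.asarray(m, dtype=np.float64), minlength=q)


def uniform_voxel_masses_from_balls(b: np.ndarray, labels: np.ndarray, q: int) -> np.ndarray:
    """Spread each ball's mass equally over its partition voxels.

    Exact right inverse of :func:`ball_masses_from_voxels`.  Raises if a ball
    owns no voxels.
    """
    b = np.asarray(b, dtype=np.float64)
    counts = np.bincount(labels, minlength=q)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"ball {empty} owns no voxels; cannot spread mass")
    return b[labels] / counts[labels]


def pngm_explicit_step(
    b: np.ndarray, net: BallNetwork, dc: float, dt: float, theta: Optional[np.ndarray] = None
) -> np.ndarray:
    """Forward-Euler ball-diffusion step.

    ``m_i' = m_i - Dc*dt * sum_j theta_ij (m_i/v_i - m_j/v_j)`` with ``dc`` in
    voxel^2/day and ``dt`` in seconds.  Conserves total mass by antisymmetry
    of the pairwise fluxes; raises on negative output (dt too large).
    """
    b = np.asarray(b, dtype=np.float64)
    a = coupling(dc, dt)
    v = net.volumes
    out = b - a * (net.theta_laplacian(theta) @ (b / v))
    scale = float(np.max(np.abs(b), initial=0.0))
    if out.size and out.min() < -1e-12 * max(scale, 1.0):
        raise StabilityError(
            f"ball-network explicit step with dt={dt} s produced negative mass {out.min():.3e}"
        )
    return out


def pngm_implicit_step(
    b: np.ndarray,
    net: BallNetwork,
    dc: float,
    dt: float,
    theta: Optional[np.ndarray] = None,
    tol: float = 1e-12,
    maxiter: int | None = None,
) -> np.ndarray:
    """Backward-Euler ball-diffusion step.

    Solved in concentration variables where the system matrix
    ``diag(v) + Dc*dt * L_theta`` is symmetric positive definite, by PCG.
    """
    b = np.asarray(b, dtype=np.float64)
    a = coupling(dc, dt)
    v = net.volumes
    lap = net.theta_laplacian(theta)
    a_mat = sp.diags(v) + a * lap
    diag = v + a * lap.diagonal()
    c = pcg_solve(a_mat.tocsr(), b, 1.0 / diag, tol=tol, maxiter=maxiter)
    return v * c
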