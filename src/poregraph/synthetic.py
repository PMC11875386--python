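"""Seeded synthetic pore geometries and initial conditions.

Real micro-CT pore spaces are large (hundreds of megavoxels); everything in
this package is testable at desk scale against synthetic geometries instead:
connected Boolean ball packings (the shape the ball-network model assumes),
all-pore chains (whose path-graph Laplacian has a closed-form spectrum),
slabs and full cubes.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse.csgraph as csgraph
import scipy.spatial.distance as ssd

from .balls import Ball, voxelize_balls
from .graph import VoxelGraph, build_voxel_graph, connected_components
from .image import BinaryImage3D, PORE, SOLID

__all__ = [
    "SynthGeometrySpec",
    "generate_ball_packing",
    "generate_chain_image",
    "generate_slab_image",
    "generate_full_cube",
    "random_dom_distribution",
]


@dataclass
class SynthGeometrySpec:
    """Specification of a synthetic geometry.

    For ball packings either ``n_balls`` (fixed count) or ``porosity`` (balls
    are added until the voxelized porosity reaches the target) drives the
    generator.  Radii are in voxel units, minimum 2.0 so the voxelization is
    non-degenerate.  Desk-scale defaults: 48^3 voxels, ~20 balls.
    """

    kind: str = "ball_packing"   # ball_packing | slab | chain | full_cube
    dims: tuple[int, int, int] = (48, 48, 48)
    n_balls: int = 20
    radius_range: tuple[float, float] = (3.0, 6.0)
    porosity: Optional[float] = None
    connected: bool = True
    seed: int = 0
    max_retries: int = 100

    def validate(self) -> None:
        if self.kind not in ("ball_packing", "slab", "chain", "full_cube"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if min(self.dims) < 2:
            raise ValueError("dims must be at least 2 per axis")
        lo, hi = self.radius_range
        if not (2.0 <= lo <= hi):
            raise ValueError("radii must satisfy 2.0 <= min <= max")
        if self.porosity is not None and not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity target must lie in (0, 1)")


def _ball_adjacency_connected(balls: list[Ball]) -> bool:
    centers = np.array([b.center for b in balls])
    radii = np.array([b.radius for b in balls])
    d = ssd.squareform(ssd.pdist(centers)) if len(balls) > 1 else np.zeros((1, 1))
    adj = (d < radii[:, None] + radii[None, :]) & ~np.eye(len(balls), dtype=bool)
    n_comp, _ = csgraph.connected_components(adj.astype(np.int8), directed=False)
    return n_comp == 1


def _sample_packing(spec: SynthGeometrySpec, rng: np.random.Generator) -> list[Ball]:
    lo, hi = spec.radius_range
    dims = np.asarray(spec.dims, dtype=float)

    def sample_center(r: float) -> np.ndarray:
        return rng.uniform(r + 0.5, dims - r - 0.5)

    def fits(center: np.ndarray, r: float) -> bool:
        return bool(np.all(center >= r) and np.all(center <= dims - r))

    r0 = rng.uniform(lo, hi)
    balls = [Ball(center=tuple(sample_center(r0)), radius=r0)]

    target_count = None if spec.porosity is not None else spec.n_balls
    mask = None
    if spec.porosity is not None:
        mask = voxelize_balls(balls, spec.dims).values == PORE

    while True:
        if target_count is not None and len(balls) >= target_count:
            break
        if mask is not None and mask.mean() >= spec.porosity:
            break
        r = rng.uniform(lo, hi)
        placed = False
        for _ in range(50):
            if spec.connected:
                anchor = balls[rng.integers(len(balls))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                # Strict overlap with a healthy lens so the voxelized pore
                # space is connected too, not just the ball graph.
                dist = rng.uniform(0.4, 0.8) * (anchor.radius + r)
                center = np.asarray(anchor.center) + dist * direction
            else:
                center = sample_center(r)
            if fits(center, r):
                balls.append(Ball(center=tuple(center), radius=r))
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a ball inside the domain")
        if mask is not None:
            mask |= voxelize_balls([balls[-1]], spec.dims).values == PORE
    return balls


def generate_ball_packing(spec: SynthGeometrySpec) -> tuple[list[Ball], BinaryImage3D]:
    """Random (seeded) overlapping-ball packing and its voxelization.

    When ``spec.connected`` is set, each new ball is attached to strictly
    overlap an existing one, so the ball adjacency graph is connected by
    construction; the voxel graph of the union is then verified to form a
    single component and the packing is resampled otherwise (at most
    ``max_retries`` times).
    """
    spec.validate()
    if spec.kind != "ball_packing":
        raise ValueError("spec.kind must be 'ball_packing'")
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_retries):
        balls = _sample_packing(spec, rng)
        image = voxelize_balls(balls, spec.dims)
        if not spec.connected:
            return balls, image
        if not _ball_adjacency_connected(balls):
            continue
        graph = build_voxel_graph(image)
        labels = connected_components(graph)
        if labels.size and labels.max() == 0:
            return balls, image
    raise RuntimeError(
        f"no connected packing found in {spec.max_retries} attempts for spec {spec}"
    )


def generate_chain_image(length: int) -> BinaryImage3D:
    """L x 1 x 1 all-pore chain; its Laplacian is the path-graph Laplacian
    with eigenvalues ``2 - 2 cos(k pi / L)``, k = 0..L-1."""
    if length < 2:
        raise ValueError("chain length must be >= 2")
    return BinaryImage3D(np.full((length, 1, 1), PORE, dtype=np.uint8))


def generate_slab_image(dims: tuple[int, int, int], thickness: int, axis: int = 2) -> BinaryImage3D:
    """Solid block with a pore slab of the given thickness at the low end of an axis."""
    if not 1 <= thickness <= dims[axis]:
        raise ValueError("thickness must lie in [1, extent]")
    vals = np.full(dims, SOLID, dtype=np.uint8)
    sl = [slice(None)] * 3
    sl[axis] = slice(0, thickness)
    vals[tuple(sl)] = PORE
    return BinaryImage3D(vals)


def generate_full_cube(dims: tuple[int, int, int]) -> BinaryImage3D:
    """All-pore volume."""
    return BinaryImage3D(np.full(dims, PORE, dtype=np.uint8))


def random_dom_distribution(
    graph: VoxelGraph,
    total_mass_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random nonnegative per-voxel masses with an exactly preserved total.

    The total is drawn uniformly from ``total_mass_range``; per-voxel shares
    come from normalizing i.i.d. uniform weights (a flat-Dirichlet-like
    allocation).
    """
    if graph.n == 0:
        raise ValueError("graph has no pore voxels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = total_mass_range
    total = rng.uniform(lo, hi)
    w = rng.random(graph.n)
    return w / w.sum() * total
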