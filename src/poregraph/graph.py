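"""Voxel adjacency graph of the pore space and its Laplacian.

Every pore voxel (tag 0) becomes a node; two nodes are joined iff their voxels
share a face (6-connectivity, Manhattan distance exactly 1).  Boundary voxels
simply have fewer neighbours, which realises the closed-system zero-flux
boundary with no extra machinery.

Node ordering is raster order with z as the outermost loop, then y, then x
innermost, so node ids are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

from .image import PORE, BinaryImage3D

__all__ = [
    "VoxelGraph",
    "build_voxel_graph",
    "laplacian",
    "connected_components",
]


@dataclass(frozen=True)
class VoxelGraph:
    """Adjacency graph of pore voxels.

    Attributes
    ----------
    shape
        Dims ``(nx, ny, nz)`` of the source image.
    node_coords
        ``(n, 3)`` integer array of 0-based voxel coordinates ``(x, y, z)``,
        row ``i`` for node ``i``, in raster order (z outer, y middle, x inner).
    edges
        ``(m, 2)`` array of node-id pairs with ``i < j``, lexicographically
        sorted; each pair joins voxels at Manhattan distance 1.
    """

    shape: tuple[int, int, int]
    node_coords: np.ndarray
    edges: np.ndarray

    @property
    def n(self) -> int:
        return len(self.node_coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def node_index_volume(self) -> np.ndarray:
        """3D int array mapping voxel -> node id, -1 on solid voxels."""
        vol = np.full(self.shape, -1, dtype=np.int64)
        x, y, z = self.node_coords.T
        vol[x, y, z] = np.arange(self.n)
        return vol

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix."""
        if self.n_edges == 0:
            return sp.csr_matrix((self.n, self.n))
        i, j = self.edges.T
        data = np.ones(2 * self.n_edges)
        return sp.csr_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n),
        )


def build_voxel_graph(image: BinaryImage3D) -> VoxelGraph:
    """Build the 6-connectivity pore graph of a binary image.

    An all-solid image yields a valid empty graph (n = 0).  Non-binary input
    is rejected by :class:`~poregraph.image.BinaryImage3D` itself.
    """
    vals = image.values
    pore = vals == PORE

    # Node ids in raster order: z outer, y middle, x inner.
    order = pore.transpose(2, 1, 0)  # [z, y, x]
    ids_zyx = np.full(order.shape, -1, dtype=np.int64)
    ids_zyx[order] = np.arange(int(order.sum()))
    idv = ids_zyx.transpose(2, 1, 0)  # back to [x, y, z]

    zz, yy, xx = np.nonzero(order)
    coords = np.column_stack([xx, yy, zz]).astype(np.int64)

    pairs = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a = idv[tuple(lo)]
        b = idv[tuple(hi)]
        mask = (a >= 0) & (b >= 0)
        if mask.any():
            pairs.append(np.column_stack([a[mask], b[mask]]))
    if pairs:
        e = np.concatenate(pairs)
        e.sort(axis=1)
        e = e[np.lexsort((e[:, 1], e[:, 0]))]
    else:
        e = np.empty((0, 2), dtype=np.int64)
    return VoxelGraph(shape=image.dims, node_coords=coords, edges=e)


def laplacian(graph: VoxelGraph) -> sp.csr_matrix:
    """Graph Laplacian: degrees on the diagonal, -1 per edge; rows sum to 0."""
    n = graph.n
    deg = sp.diags(graph.degrees.astype(np.float64), shape=(n, n), format="csr")
    if graph.n_edges:
        return (deg - graph.adjacency()).tocsr()
    return deg


def connected_components(graph: VoxelGraph) -> np.ndarray:
    """Label nodes by connected component.

    Labels are renumbered so component k is the one containing the smallest
    not-yet-seen node id (deterministic regardless of backend ordering).
    """
    if graph.n == 0:
        return np.empty(0, dtype=np.int64)
    _, raw = _cc(graph.adjacency(), directed=False)
    # Renumber labels by first occurrence along the node ordering.
    _, first = np.unique(raw, return_index=True)
    order = np.argsort(first)
    relabel = np.empty(len(order), dtype=np.int64)
    relabel[order] = np.arange(len(order))
    return relabel[raw]
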