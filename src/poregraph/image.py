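"""3D binary pore-space images.

A volume is a 3D array of {0, 1} voxel tags where 0 marks pore (water-filled
void under full saturation) and 1 marks solid.  Arrays are indexed ``[x, y, z]``
with shape ``(nx, ny, nz)``; the z axis is the stacking axis of multi-page TIFF
files (see :mod:`poregraph.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PORE = 0
SOLID = 1


@dataclass(frozen=True)
class BinaryImage3D:
    """Binary pore/solid volume.

    Parameters
    ----------
    values
        3D uint8 array, 0 = pore, 1 = solid, shape ``(nx, ny, nz)``.
    voxel_edge_length
        Physical edge length of one voxel (arbitrary length unit, default one
        voxel unit).  Only used for physical-volume bookkeeping; the solvers
        work in voxel units.
    """

    values: np.ndarray
    voxel_edge_length: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"expected a 3D array with positive dims, got shape {arr.shape}")
        bad = np.setdiff1d(np.unique(arr), [PORE, SOLID])
        if bad.size:
            raise ValueError(f"image values must be 0 (pore) or 1 (solid); found value {bad[0]!r}")
        if self.voxel_edge_length <= 0:
            raise ValueError("voxel_edge_length must be positive")
        object.__setattr__(self, "values", np.ascontiguousarray(arr, dtype=np.uint8))

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def n_pore(self) -> int:
        return int(np.count_nonzero(self.values == PORE))

    @property
    def porosity(self) -> float:
        return self.n_pore / self.values.size

    def physical_volume(self) -> float:
        """Total sample volume in (voxel_edge_length)^3 units."""
        return physical_volume(self.dims, self.voxel_edge_length)


def physical_volume(dims: tuple[int, int, int], voxel_edge_length: float) -> float:
    """Sample volume of a ``dims`` voxel grid with the given voxel edge length."""
    nx, ny, nz = dims
    if min(dims) < 1 or voxel_edge_length <= 0:
        raise ValueError("dims must be positive and voxel_edge_length > 0")
    return float(nx) * float(ny) * float(nz) * float(voxel_edge_length) ** 3
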