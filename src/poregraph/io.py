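"""File formats: binary volumes, ball sets, graphs, tables and run manifests.

Volume convention: internally a volume is indexed ``[x, y, z]``.  Multi-page
TIFFs hold one z-slice per page with x as the row axis and y as the column
axis, so a TIFF with 3 pages of 4x5 pixels maps to dims (4, 5, 3).  Raw
volumes are uint8 streams in the same page order (z slowest, then x, then y).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .balls import Ball
from .graph import VoxelGraph
from .image import BinaryImage3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_balls_csv",
    "write_balls_csv",
    "save_graph",
    "load_graph",
    "write_table",
    "write_manifest",
]

#: CSV floats are written at 12 significant digits so identical runs produce
#: byte-identical outputs.
FLOAT_FORMAT = "%.12g"


def _to_pages(image: BinaryImage3D) -> np.ndarray:
    return image.values.transpose(2, 0, 1)  # (z, x, y)


def _from_pages(pages: np.ndarray) -> np.ndarray:
    if pages.ndim == 2:
        pages = pages[None]
    return pages.transpose(1, 2, 0)  # (x, y, z)


def read_volume(
    path: str | Path,
    dims: Optional[tuple[int, int, int]] = None,
    binarize: bool = False,
    voxel_edge_length: float = 1.0,
) -> BinaryImage3D:
    """Read a multi-page TIFF or raw uint8 volume as a binary image.

    Raw files require ``dims``.  Without ``binarize``, any value outside
    {0, 1} is rejected; with it, nonzero values are treated as solid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = _from_pages(np.asarray(tifffile.imread(path)))
        if dims is not None and tuple(arr.shape) != tuple(dims):
            raise ValueError(f"volume {path} has dims {arr.shape}, expected {tuple(dims)}")
    else:
        if dims is None:
            raise ValueError("raw volumes need explicit dims")
        flat = np.fromfile(path, dtype=np.uint8)
        nx, ny, nz = dims
        if flat.size != nx * ny * nz:
            raise ValueError(
                f"raw volume {path} holds {flat.size} voxels, expected {nx * ny * nz} for dims {dims}"
            )
        arr = _from_pages(flat.reshape(nz, nx, ny))
    if binarize:
        arr = (arr != 0).astype(np.uint8)
    return BinaryImage3D(arr, voxel_edge_length=voxel_edge_length)


def write_volume(image: BinaryImage3D, path: str | Path) -> None:
    """Write a volume as multi-page TIFF or raw uint8 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, _to_pages(image), photometric="minisblack")
    else:
        _to_pages(image).tofile(path)


def read_balls_csv(path: str | Path) -> list[Ball]:
    """Read a ball set from a CSV with columns x, y, z, r."""
    df = pd.read_csv(path)
    missing = {"x", "y", "z", "r"} - set(df.columns)
    if missing:
        raise ValueError(f"ball CSV {path} lacks columns {sorted(missing)}")
    return [Ball(center=(row.x, row.y, row.z), radius=row.r) for row in df.itertuples()]


def write_balls_csv(balls: Sequence[Ball], path: str | Path) -> None:
    df = pd.DataFrame(
        [(b.center[0], b.center[1], b.center[2], b.radius) for b in balls],
        columns=["x", "y", "z", "r"],
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def save_graph(graph: VoxelGraph, path: str | Path) -> None:
    """Save a voxel graph as a compressed edge list plus coordinate table."""
    np.savez_compressed(
        path,
        shape=np.asarray(graph.shape, dtype=np.int64),
        node_coords=graph.node_coords,
        edges=graph.edges,
    )


def load_graph(path: str | Path) -> VoxelGraph:
    with np.load(path) as data:
        return VoxelGraph(
            shape=tuple(int(v) for v in data["shape"]),
            node_coords=data["node_coords"],
            edges=data["edges"],
        )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV writer with the package-wide fixed float format."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    inputs: Sequence[str | Path] = (),
    seed: Optional[int] = None,
) -> None:
    """Write the run manifest: config snapshot, seed, version, input checksums."""
    from . import __version__

    manifest = {
        "version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
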