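"""Voxel phantoms: density grids with geometry metadata.

A phantom is a rectilinear grid of mass densities (g/cm^3) in patient
coordinates; ``origin`` is the corner of the first voxel and voxel
centers sit at ``origin + (index + 0.5) * spacing``.  Zero density is
treated as vacuum (particles stream through without interacting).

The native container is an ``.npz`` archive with keys ``density``,
``origin_cm``, ``spacing_cm`` and a format tag; CT-number grids are
converted through a user-supplied monotone HU-to-density table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["VoxelPhantom", "build_phantom_from_ct", "read_phantom",
           "write_phantom"]

_FORMAT = "tomovsm-phantom-v1"


@dataclass(frozen=True)
class VoxelPhantom:
    origin_cm: tuple[float, float, float]
    spacing_cm: tuple[float, float, float]
    density: np.ndarray  # (nx, ny, nz), g/cm^3

    def __post_init__(self) -> None:
        dens = np.ascontiguousarray(self.density, dtype=np.float64)
        object.__setattr__(self, "density", dens)
        if dens.ndim != 3:
            raise ValueError("density must be a 3D array")
        if np.any(dens < 0):
            raise ValueError("densities must be >= 0")
        if any(s <= 0 for s in self.spacing_cm):
            raise ValueError("voxel spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def extent_cm(self) -> np.ndarray:
        """(min, max) corner per axis, shape (2, 3)."""
        lo = np.asarray(self.origin_cm)
        hi = lo + np.asarray(self.dims) * np.asarray(self.spacing_cm)
        return np.stack([lo, hi])

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return (self.origin_cm[axis]
                + (np.arange(n) + 0.5) * self.spacing_cm[axis])

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing_cm))


def build_phantom_from_ct(hu_grid: np.ndarray, density_table,
                          origin_cm=(0.0, 0.0, 0.0),
                          spacing_cm=(0.1953, 0.1953, 0.3)) -> VoxelPhantom:
    """Convert a CT-number grid to densities via a monotone lookup table.

    ``density_table`` maps HU to g/cm^3 and may be a dict or a pair of
    arrays ``(hu, density)``; values are linearly interpolated and
    clamped to the table's end points.
    """
    if isinstance(density_table, dict):
        hu_pts = np.asarray(sorted(density_table), dtype=float)
        rho_pts = np.asarray([density_table[h] for h in sorted(density_table)],
                             dtype=float)
    else:
        hu_pts, rho_pts = (np.asarray(a, dtype=float) for a in density_table)
    if np.any(np.diff(hu_pts) <= 0) or np.any(np.diff(rho_pts) < 0):
        raise ValueError("density table must be monotone in HU and density")
    rho = np.interp(np.asarray(hu_grid, dtype=float), hu_pts, rho_pts)
    return VoxelPhantom(tuple(origin_cm), tuple(spacing_cm), rho)


def write_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    np.savez_compressed(path, format=_FORMAT,
                        density=phantom.density.astype(np.float32),
                        origin_cm=np.asarray(phantom.origin_cm),
                        spacing_cm=np.asarray(phantom.spacing_cm))


def read_phantom(path: str | Path) -> VoxelPhantom:
    with np.load(path) as data:
        if str(data.get("format", "")) != _FORMAT:
            raise ValueError(f"{path} is not a {_FORMAT} container")
        return VoxelPhantom(tuple(data["origin_cm"]), tuple(data["spacing_cm"]),
                            data["density"].astype(np.float64))
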