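"""Shared Cartesian lattice construction.

All molecules (training, test and prediction sets jointly) are snapped onto a
single regular grid: atomic coordinates are rounded to the nearest lattice
point (half-way cases round away from zero), padding is added around the
snapped extremes, and the point count per axis is ceil(range/spacing) + 1 so
both padded extremes are themselves lattice points.  Grid points are
enumerated x-fastest; the ordering is a pure bookkeeping convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .chemio import MoleculeSet

__all__ = ["GridSpec", "snap_coordinates", "build_grid", "grid_points"]


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]  # minimum corner after padding, Å
    spacing: float                      # Å
    dims: tuple[int, int, int]          # points per axis
    padding: float                      # Å

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.padding < 0:
            raise ValueError("grid padding must be >= 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def upper(self) -> np.ndarray:
        """Maximum corner, origin + (dims - 1) * spacing."""
        return np.asarray(self.origin) + (np.asarray(self.dims) - 1) * self.spacing

    def flat_index(self, ix: int, iy: int, iz: int) -> int:
        nx, ny, _ = self.dims
        return ix + nx * (iy + ny * iz)

    def unravel(self, flat: int) -> tuple[int, int, int]:
        nx, ny, _ = self.dims
        return flat % nx, (flat // nx) % ny, flat // (nx * ny)


def snap_coordinates(coords: np.ndarray, spacing: float) -> np.ndarray:
    """Round each coordinate component to the nearest multiple of ``spacing``.

    Half-way cases round away from zero (so 0.5 with unit spacing snaps to 1,
    -0.5 to -1).  Idempotent on lattice points.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    coords = np.asarray(coords, dtype=float)
    scaled = np.abs(coords) / spacing
    return np.copysign(np.floor(scaled + 0.5), coords) * spacing


def build_grid(
    sets: MoleculeSet | Iterable[MoleculeSet],
    spacing: float = 1.0,
    padding: float = 4.0,
    snap: bool = True,
) -> GridSpec:
    """Build the lattice covering every molecule of every supplied set.

    Per axis: lo = min(snapped coords) - padding, hi = max + padding,
    dims = ceil((hi - lo)/spacing) + 1, origin = (lo_x, lo_y, lo_z).
    """
    if isinstance(sets, MoleculeSet):
        sets = [sets]
    all_coords = []
    for mset in sets:
        for mol in mset:
            if not mol.has_conformer():
                raise ValueError(f"molecule {mol.name!r} has no coordinates")
            all_coords.append(mol.coords)
    if not all_coords:
        raise ValueError("no molecules supplied to build_grid")
    coords = np.vstack(all_coords)
    if snap:
        coords = snap_coordinates(coords, spacing)
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    # tiny slack keeps exact-integer ranges from ceil-ing up through float noise
    dims = tuple(int(np.ceil((h - l) / spacing - 1e-9)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing),
                    dims=dims, padding=float(padding))


def grid_points(grid: GridSpec) -> np.ndarray:
    """All lattice points, (n_points, 3) in Å, enumerated x-fastest.

    Flat index = ix + nx*(iy + ny*iz); the first point is the origin and the
    last is origin + (dims - 1)*spacing.
    """
    nx, ny, nz = grid.dims
    ax = [np.asarray(grid.origin)[i] + grid.spacing * np.arange(n)
          for i, n in enumerate((nx, ny, nz))]
    xs, ys, zs = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
    pts = np.stack(
        [xs.transpose(2, 1, 0).ravel(),
         ys.transpose(2, 1, 0).ravel(),
         zs.transpose(2, 1, 0).ravel()],
        axis=1,
    )
    return pts
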