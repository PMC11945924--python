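"""Coefficient contour maps: scatter PLS coefficients back onto the grid and
extract percentile-thresholded isosurfaces.

Each kept column's coefficient is multiplied by the standard deviation of its
scaled column (the quantity stored during preprocessing) and scattered to its
grid point; filtered columns hold zero.  High/low levels default to the 95th/
5th percentile of the NONZERO map values — quantiles over the full map would
be collapsed to zero by the empty-space points — and meshes are extracted with
marching cubes, with vertices mapped from index space to Å.  Positive (high)
surfaces mark regions where increasing the field property is associated with
higher activity under this package's raw-similarity sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from skimage.measure import marching_cubes

from .grid import GridSpec
from .pls import QsarModel

__all__ = [
    "CoefficientMap",
    "Mesh",
    "ContourSet",
    "coefficient_map",
    "percentile_thresholds",
    "extract_isosurfaces",
    "export_contours",
    "read_obj",
    "write_cube",
]

# Fig-style color legend, exported as metadata only.
_FIELD_COLORS = {
    "S": ("yellow", "green"),
    "E": ("red", "blue"),
    "H": ("orange", "purple"),
    "A": ("teal", "purple"),
    "D": ("yellow", "gray"),
}


@dataclass
class CoefficientMap:
    field_name: str
    values: np.ndarray  # (nx, ny, nz), coefficient x scaled-field-std units
    grid: GridSpec

    def flat(self) -> np.ndarray:
        """Values in the x-fastest flat order of the grid module."""
        return self.values.transpose(2, 1, 0).ravel()


@dataclass
class Mesh:
    vertices: np.ndarray  # (n, 3), Å
    faces: np.ndarray     # (m, 3), int vertex indices

    @property
    def empty(self) -> bool:
        return len(self.vertices) == 0

    @classmethod
    def empty_mesh(cls) -> "Mesh":
        return cls(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))


@dataclass
class ContourSet:
    field_name: str
    high_threshold: float
    low_threshold: float
    high_mesh: Mesh
    low_mesh: Mesh
    labels: dict = dc_field(default_factory=dict)


def coefficient_map(
    model: QsarModel, grid: GridSpec, field_name: str
) -> CoefficientMap:
    """Scatter b_j * s_j of one field's kept columns onto the 3D grid."""
    fields_present = {c.field_name for c in model.columns}
    if field_name not in fields_present:
        raise ValueError(
            f"field {field_name!r} not in model (has {sorted(fields_present)})"
        )
    nx, ny, nz = grid.dims
    values = np.zeros((nx, ny, nz))
    for b, col in zip(model.coefficients, model.columns):
        if col.field_name != field_name:
            continue
        ix, iy, iz = grid.unravel(col.grid_index)
        values[ix, iy, iz] = b * col.scale_std
    return CoefficientMap(field_name=field_name, values=values, grid=grid)


def percentile_thresholds(
    cmap: CoefficientMap, top_fraction: float = 0.05
) -> tuple[float, float]:
    """(low, high) levels at the top_fraction tails of the nonzero map values."""
    if not 0 < top_fraction < 0.5:
        raise ValueError("top_fraction must be in (0, 0.5)")
    nonzero = cmap.values[cmap.values != 0]
    if nonzero.size == 0 or np.ptp(nonzero) == 0:
        raise ValueError(f"no contourable signal in field {cmap.field_name!r}")
    low = float(np.quantile(nonzero, top_fraction))
    high = float(np.quantile(nonzero, 1.0 - top_fraction))
    return low, high


def _mesh_at(cmap: CoefficientMap, level: float) -> Mesh:
    values = cmap.values
    if not values.min() < level < values.max():
        warnings.warn(
            f"threshold {level:g} outside map range of field {cmap.field_name!r}; "
            "empty mesh"
        )
        return Mesh.empty_mesh()
    verts, faces, _, _ = marching_cubes(values, level=level)
    verts = np.asarray(cmap.grid.origin) + verts * cmap.grid.spacing
    return Mesh(vertices=verts, faces=faces.astype(int))


def extract_isosurfaces(
    cmap: CoefficientMap, thresholds: tuple[float, float]
) -> ContourSet:
    """Marching-cubes meshes at the (low, high) levels, vertices in Å."""
    low, high = thresholds
    favorable, unfavorable = _FIELD_COLORS.get(cmap.field_name, ("high", "low"))
    return ContourSet(
        field_name=cmap.field_name,
        high_threshold=high,
        low_threshold=low,
        high_mesh=_mesh_at(cmap, high),
        low_mesh=_mesh_at(cmap, low),
        labels={
            "high": {"meaning": "favorable", "color": favorable},
            "low": {"meaning": "unfavorable", "color": unfavorable},
        },
    )


def _write_obj(mesh: Mesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coefficient-map isosurface\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_obj(path: str | Path) -> Mesh:
    """Minimal OBJ reader (v/f records) for round-trip verification."""
    verts, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            faces.append([int(t.split("/")[0]) - 1 for t in parts[1:4]])
    return Mesh(
        np.array(verts).reshape(-1, 3),
        np.array(faces, dtype=int).reshape(-1, 3),
    )


def _write_vtk(mesh: Mesh, path: Path) -> None:
    """Legacy ASCII VTK polydata."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoefficient-map isosurface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def export_contours(
    cset: ContourSet,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("obj",),
) -> list[Path]:
    """Write high/low meshes as OBJ and/or legacy VTK; filenames encode field+sign."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sign, mesh in (("high", cset.high_mesh), ("low", cset.low_mesh)):
        for fmt in formats:
            if fmt not in ("obj", "vtk"):
                raise ValueError(f"unknown mesh format {fmt!r}")
            path = out_dir / f"contour_{cset.field_name}_{sign}.{fmt}"
            (_write_obj if fmt == "obj" else _write_vtk)(mesh, path)
            written.append(path)
    return written


_BOHR_PER_ANGSTROM = 1.0 / 0.52917721092


def write_cube(cmap: CoefficientMap, path: str | Path) -> Path:
    """Export a coefficient map as a Gaussian cube volume (no atoms block)."""
    path = Path(path)
    nx, ny, nz = cmap.grid.dims
    origin = np.asarray(cmap.grid.origin) * _BOHR_PER_ANGSTROM
    step = cmap.grid.spacing * _BOHR_PER_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"coefficient map, field {cmap.field_name}\n")
        fh.write("generated by comsia\n")
        fh.write(f"{0:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {step:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {step:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {step:12.6f}\n")
        flat = cmap.values.ravel()  # cube order: x slowest, z fastest
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v:13.5E}" for v in flat[start:start + 6]) + "\n")
    return path
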