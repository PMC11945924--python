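"""Gaussian similarity fields on the shared grid.

Each of the five CoMSIA property fields reduces to a set of weighted Gaussian
sources: the field value at grid point q is sum_i w_i * exp(-alpha * |q-c_i|^2)
with attenuation alpha (Å^-2, default 0.3).  Atom-centered sources carry

  steric        w = vdW radius cubed (Å^3)
  electrostatic w = Gasteiger partial charge (signed)
  hydrophobic   w = Crippen atomic logP contribution (signed)

while the hydrogen-bond donor and acceptor layers use unit-weight pseudoatoms
placed 1.9 Å from the parent heavy atom: donors along each X-H bond ray,
acceptors along idealized lone-pair directions from the atom's hybridization.
Fields are the raw similarity sums under an implicit +1 probe; no probe-sign
flip is applied (PLS is invariant to it up to coefficient sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .chemio import AtomRecord, Hybridization, Molecule, MoleculeSet
from .grid import GridSpec, grid_points, snap_coordinates

__all__ = [
    "FIELD_NAMES",
    "FieldConfig",
    "GaussianSource",
    "FieldTensor",
    "gaussian_accumulate",
    "steric_sources",
    "electrostatic_sources",
    "hydrophobic_sources",
    "donor_pseudoatoms",
    "acceptor_pseudoatoms",
    "compute_all_fields",
]

FIELD_NAMES = ("S", "E", "H", "A", "D")

_TET_HALF = np.deg2rad(109.471 / 2.0)     # half tetrahedral angle
_TET_FROM_AXIS = np.deg2rad(180.0 - 109.471)  # lone-pair tilt off the anti-bond axis
_SP2_OFF_AXIS = np.deg2rad(60.0)          # 120° from the bond == 60° from anti-bond


@dataclass(frozen=True)
class FieldConfig:
    """Parameters of the field calculation.

    alpha : Gaussian attenuation, Å^-2.
    fields_enabled : subset of "SEHAD" (order-insensitive; canonical S,E,H,A,D
        ordering is always used in outputs).
    pseudo_distance : heavy-atom-to-pseudoatom distance, Å.
    clash_factor : a pseudoatom closer than clash_factor * vdW(other atom) to
        any atom other than its parent (and the parent's bonded hydrogens) is
        rejected as sterically implausible.
    snap : snap atom-centered sources to the lattice (pseudoatom geometry is
        always computed from raw coordinates, see donor/acceptor builders).
    include_hydrogens : include explicit H atoms as steric/electrostatic/
        hydrophobic sources.
    donor_beyond_h : place donor pseudoatoms pseudo_distance beyond the H along
        the X-H ray instead of pseudo_distance from the heavy atom.
    """

    alpha: float = 0.3
    fields_enabled: str = "SEHAD"
    pseudo_distance: float = 1.9
    clash_factor: float = 0.7
    snap: bool = True
    include_hydrogens: bool = True
    donor_beyond_h: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.pseudo_distance <= 0:
            raise ValueError("pseudo_distance must be > 0")
        enabled = self.enabled_fields()
        if not enabled:
            raise ValueError("fields_enabled must name at least one of S,E,H,A,D")
        unknown = set(self.fields_enabled.upper()) - set(FIELD_NAMES)
        if unknown:
            raise ValueError(f"unknown field codes: {sorted(unknown)}")

    def enabled_fields(self) -> tuple[str, ...]:
        wanted = set(self.fields_enabled.upper())
        return tuple(f for f in FIELD_NAMES if f in wanted)


@dataclass(frozen=True)
class GaussianSource:
    center: np.ndarray  # (3,), Å
    weight: float


@dataclass
class FieldTensor:
    """Per-molecule, per-field values at every grid point.

    values has shape (n_molecules, n_fields, n_grid_points) with grid points
    in the x-fastest flat order of the grid module.
    """

    values: np.ndarray
    grid: GridSpec
    field_names: tuple[str, ...]
    molecule_names: list[str]
    role: str = "train"
    warnings: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field tensor contains non-finite values")
        n_mol, n_fields, n_pts = self.values.shape
        if n_fields != len(self.field_names) or n_pts != self.grid.n_points:
            raise ValueError("field tensor shape inconsistent with grid/fields")
        if n_mol != len(self.molecule_names):
            raise ValueError("field tensor shape inconsistent with molecule count")


def gaussian_accumulate(
    sources: Sequence[GaussianSource],
    grid: GridSpec | np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Evaluate sum_i w_i exp(-alpha |q - c_i|^2) at every grid point.

    ``grid`` may be a GridSpec or a precomputed (n, 3) point array.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    points = grid if isinstance(grid, np.ndarray) else grid_points(grid)
    if not sources:
        return np.zeros(len(points))
    centers = np.array([s.center for s in sources], dtype=float)
    weights = np.array([s.weight for s in sources], dtype=float)
    d2 = cdist(points, centers, metric="sqeuclidean")
    return np.exp(-alpha * d2) @ weights


def _included_atoms(mol: Molecule, include_h: bool) -> list[AtomRecord]:
    if not mol.annotated:
        raise ValueError(f"molecule {mol.name!r} is not annotated")
    return [a for a in mol.atoms if include_h or a.element != "H"]


def _centers(
    atoms: list[AtomRecord], cfg: FieldConfig, spacing: float
) -> list[np.ndarray]:
    if cfg.snap:
        return [snap_coordinates(a.coords, spacing) for a in atoms]
    return [a.coords for a in atoms]


def steric_sources(
    mol: Molecule, cfg: FieldConfig = FieldConfig(), spacing: float = 1.0
) -> list[GaussianSource]:
    """One source per atom, weighted by the cube of its van der Waals radius."""
    atoms = _included_atoms(mol, cfg.include_hydrogens)
    for a in atoms:
        if not np.isfinite(a.vdw_radius) or a.vdw_radius <= 0:
            raise ValueError(f"missing vdW radius for atom {a.index} of {mol.name!r}")
    return [
        GaussianSource(center=c, weight=a.vdw_radius ** 3)
        for a, c in zip(atoms, _centers(atoms, cfg, spacing))
    ]


def electrostatic_sources(
    mol: Molecule, cfg: FieldConfig = FieldConfig(), spacing: float = 1.0
) -> list[GaussianSource]:
    """One source per atom, weighted by its (signed) Gasteiger partial charge."""
    atoms = _included_atoms(mol, cfg.include_hydrogens)
    return [
        GaussianSource(center=c, weight=a.gasteiger_charge)
        for a, c in zip(atoms, _centers(atoms, cfg, spacing))
    ]


def hydrophobic_sources(
    mol: Molecule, cfg: FieldConfig = FieldConfig(), spacing: float = 1.0
) -> list[GaussianSource]:
    """One source per atom, weighted by its Crippen atomic logP contribution."""
    atoms = _included_atoms(mol, cfg.include_hydrogens)
    return [
        GaussianSource(center=c, weight=a.crippen_logp)
        for a, c in zip(atoms, _centers(atoms, cfg, spacing))
    ]


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    if n < 1e-8:
        return None
    return v / n


def _clash_ok(
    pos: np.ndarray, mol: Molecule, parent: AtomRecord, cfg: FieldConfig
) -> bool:
    """False when pos sits inside clash_factor * vdW of a non-parent atom.

    The parent's bonded hydrogens are exempt (a donor pseudoatom necessarily
    sits on top of its own H).
    """
    exempt = {parent.index}
    h_set = {tuple(np.round(h, 6)) for h in parent.attached_h_positions}
    for a in mol.atoms:
        if a.index in exempt:
            continue
        if a.element == "H" and tuple(np.round(a.coords, 6)) in h_set:
            continue
        if np.linalg.norm(pos - a.coords) < cfg.clash_factor * a.vdw_radius:
            return False
    return True


def donor_pseudoatoms(
    mol: Molecule, cfg: FieldConfig = FieldConfig(), collect: list[str] | None = None
) -> list[GaussianSource]:
    """Unit-weight pseudoatoms along each donor X-H ray.

    Default placement: pseudo_distance from the heavy atom along the X-H
    direction; with ``donor_beyond_h`` the site sits pseudo_distance beyond
    the hydrogen instead.  Geometry uses raw (unsnapped) coordinates so the
    parent-distance invariant holds exactly.  Clash-filtered.
    """
    sources: list[GaussianSource] = []
    for atom in mol.atoms:
        if not atom.is_donor:
            continue
        if not atom.attached_h_positions:
            msg = f"donor atom {atom.index} of {mol.name!r} has no locatable H; skipped"
            warnings.warn(msg)
            if collect is not None:
                collect.append(msg)
            continue
        for h in atom.attached_h_positions:
            direction = _unit(h - atom.coords)
            if direction is None:
                continue
            if cfg.donor_beyond_h:
                pos = h + cfg.pseudo_distance * direction
            else:
                pos = atom.coords + cfg.pseudo_distance * direction
            if _clash_ok(pos, mol, atom, cfg):
                sources.append(GaussianSource(center=pos, weight=1.0))
    return sources


def _lone_pair_directions(
    atom: AtomRecord, mol: Molecule, collect: list[str] | None
) -> list[np.ndarray]:
    """Idealized VSEPR lone-pair unit vectors for an acceptor atom."""
    rdmol = mol.rdmol
    nbr_pos = [
        np.array(rdmol.GetConformer().GetAtomPosition(n.GetIdx()))
        for n in rdmol.GetAtomWithIdx(atom.index).GetNeighbors()
    ]
    vs = []
    for p in nbr_pos:
        u = _unit(p - atom.coords)
        if u is not None:
            vs.append(u)

    def fallback(reason: str) -> list[np.ndarray]:
        if collect is not None:
            collect.append(
                f"degenerate acceptor geometry at atom {atom.index} of "
                f"{mol.name!r} ({reason}); using single anti-bond direction"
            )
        anti = _unit(-np.sum(vs, axis=0)) if vs else None
        return [anti] if anti is not None else []

    if not vs:
        return fallback("isolated atom")
    anti = _unit(-np.sum(vs, axis=0))

    hyb, n = atom.hybridization, len(vs)
    if hyb == Hybridization.SP3:
        if n >= 3:
            return [anti] if anti is not None else fallback("opposed bonds")
        if n == 2:
            perp = _unit(np.cross(vs[0], vs[1]))
            if perp is None or anti is None:
                return fallback("colinear bonds")
            return [
                _unit(np.cos(_TET_HALF) * anti + s * np.sin(_TET_HALF) * perp)
                for s in (+1.0, -1.0)
            ]
        # single neighbor: tripod at the tetrahedral tilt around the axis
        axis = -vs[0]
        perp = _perpendicular(axis)
        dirs = []
        for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            p = np.cos(ang) * perp + np.sin(ang) * np.cross(axis, perp)
            dirs.append(_unit(np.cos(_TET_FROM_AXIS) * axis + np.sin(_TET_FROM_AXIS) * p))
        return [d for d in dirs if d is not None]
    if hyb == Hybridization.SP2:
        if n == 1:
            normal = _sp2_plane_normal(atom, mol, vs[0])
            if normal is None:
                return fallback("no plane reference")
            axis = -vs[0]
            in_plane = _unit(np.cross(normal, axis))
            if in_plane is None:
                return fallback("colinear plane reference")
            return [
                _unit(np.cos(_SP2_OFF_AXIS) * axis + s * np.sin(_SP2_OFF_AXIS) * in_plane)
                for s in (+1.0, -1.0)
            ]
        return [anti] if anti is not None else fallback("opposed bonds")
    # sp / other: single anti-bond direction
    return [anti] if anti is not None else fallback("opposed bonds")


def _perpendicular(v: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, v)) > 0.9 * np.linalg.norm(v):
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, trial)
    return p / np.linalg.norm(p)


def _sp2_plane_normal(
    atom: AtomRecord, mol: Molecule, bond_dir: np.ndarray
) -> np.ndarray | None:
    """Normal of the sp2 plane, taken from the neighbor's other substituents."""
    rdmol = mol.rdmol
    conf = rdmol.GetConformer()
    nbr = rdmol.GetAtomWithIdx(atom.index).GetNeighbors()[0]
    nbr_pos = np.array(conf.GetAtomPosition(nbr.GetIdx()))
    for nn in nbr.GetNeighbors():
        if nn.GetIdx() == atom.index:
            continue
        arm = _unit(np.array(conf.GetAtomPosition(nn.GetIdx())) - nbr_pos)
        if arm is None:
            continue
        normal = _unit(np.cross(bond_dir, arm))
        if normal is not None:
            return normal
    return None


def acceptor_pseudoatoms(
    mol: Molecule, cfg: FieldConfig = FieldConfig(), collect: list[str] | None = None
) -> list[GaussianSource]:
    """Unit-weight pseudoatoms along idealized lone-pair directions.

    sp2 acceptors with one neighbor (carbonyl-type) get two in-plane sites at
    ±120° from the bond; sp3 acceptors complete tetrahedral geometry; sp and
    geometry-degenerate cases fall back to a single anti-bond direction.
    Raw-coordinate geometry; clash-filtered.
    """
    sources: list[GaussianSource] = []
    for atom in mol.atoms:
        if not atom.is_acceptor:
            continue
        for direction in _lone_pair_directions(atom, mol, collect):
            pos = atom.coords + cfg.pseudo_distance * direction
            if _clash_ok(pos, mol, atom, cfg):
                sources.append(GaussianSource(center=pos, weight=1.0))
    return sources


_SOURCE_BUILDERS = {
    "S": steric_sources,
    "E": electrostatic_sources,
    "H": hydrophobic_sources,
}


def compute_all_fields(
    mset: MoleculeSet, grid: GridSpec, cfg: FieldConfig = FieldConfig()
) -> FieldTensor:
    """Evaluate every enabled field for every molecule on the shared grid."""
    names = cfg.enabled_fields()
    points = grid_points(grid)
    notes: list[str] = []
    values = np.zeros((len(mset), len(names), grid.n_points))
    for mi, mol in enumerate(mset):
        for fi, fname in enumerate(names):
            if fname in _SOURCE_BUILDERS:
                sources = _SOURCE_BUILDERS[fname](mol, cfg, spacing=grid.spacing)
            elif fname == "D":
                sources = donor_pseudoatoms(mol, cfg, collect=notes)
            else:
                sources = acceptor_pseudoatoms(mol, cfg, collect=notes)
            values[mi, fi] = gaussian_accumulate(sources, points, cfg.alpha)
    return FieldTensor(
        values=values,
        grid=grid,
        field_names=names,
        molecule_names=mset.names,
        role=mset.role,
        warnings=notes,
    )
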