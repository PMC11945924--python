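"""Molecule I/O and per-atom physicochemical annotation.

Molecules enter either as pre-aligned 3D structures in MDL SDF (V2000) with an
activity data tag, or as SMILES rows in a CSV table (topology only, to be
embedded and aligned downstream).  Before field calculation every atom is
annotated with the quantities the similarity fields are built from: a van der
Waals radius from a fixed Bondi-style table (shipped so results do not depend
on toolkit versions), a Gasteiger partial charge, Crippen's atomic logP
contribution, hydrogen-bond donor/acceptor flags from an explicit SMARTS set,
and a hybridization label used for lone-pair geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

__all__ = [
    "AtomRecord",
    "Molecule",
    "MoleculeSet",
    "Hybridization",
    "VDW_RADII",
    "DEFAULT_DONOR_SMARTS",
    "DEFAULT_ACCEPTOR_SMARTS",
    "read_sdf",
    "read_smiles_table",
    "read_smarts_file",
    "annotate_atoms",
    "annotate_set",
    "write_sdf",
]

# Bondi-style van der Waals radii, Å.  Fixed data: keeps field weights
# independent of the cheminformatics library version.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "Li": 1.82, "Be": 1.53, "B": 1.92, "C": 1.70,
    "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54, "Na": 2.27, "Mg": 1.73,
    "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Zn": 1.39, "Ga": 1.87, "Ge": 2.11, "As": 1.85,
    "Se": 1.90, "Br": 1.85, "Kr": 2.02, "I": 1.98, "Xe": 2.16,
}

# Default H-bond SMARTS.  Donors: any N/O/S bearing at least one hydrogen.
# Acceptors: neutral divalent or terminal oxygen; neutral nitrogen that is not
# an amide nitrogen (amine, imine/aromatic, nitrile).  Overridable via
# read_smarts_file.
DEFAULT_DONOR_SMARTS: tuple[str, ...] = (
    "[#7;!H0]",
    "[#8;!H0]",
    "[#16;!H0]",
)
DEFAULT_ACCEPTOR_SMARTS: tuple[str, ...] = (
    "[#8;X2;!+]",
    "[#8;X1]",
    "[#7;X3;!+;!$([NX3][CX3]=[OX1])]",
    "[#7;X2;!+]",
    "[#7;X1]",
)


class Hybridization(str, Enum):
    SP = "sp"
    SP2 = "sp2"
    SP3 = "sp3"
    OTHER = "other"


@dataclass
class AtomRecord:
    """Annotation of a single atom used by the field builders."""

    index: int
    element: str
    coords: np.ndarray  # (3,), Å
    vdw_radius: float = float("nan")
    gasteiger_charge: float = float("nan")
    crippen_logp: float = float("nan")
    is_donor: bool = False
    is_acceptor: bool = False
    hybridization: Hybridization = Hybridization.OTHER
    attached_h_positions: list[np.ndarray] = field(default_factory=list)


@dataclass
class Molecule:
    name: str
    rdmol: Chem.Mol
    activity: float | None = None
    atoms: list[AtomRecord] = field(default_factory=list)
    needs_embedding: bool = False

    @property
    def coords(self) -> np.ndarray:
        """All-atom coordinate array (n_atoms, 3) in Å."""
        conf = self.rdmol.GetConformer()
        return np.array(conf.GetPositions(), dtype=float)

    @property
    def annotated(self) -> bool:
        return bool(self.atoms)

    def has_conformer(self) -> bool:
        return self.rdmol.GetNumConformers() > 0


@dataclass
class MoleculeSet:
    molecules: list[Molecule]
    role: str = "train"  # train | test | predict

    def __post_init__(self) -> None:
        names = [m.name for m in self.molecules]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate molecule names in set: {dup}")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.molecules]

    @property
    def activities(self) -> list[float | None]:
        return [m.activity for m in self.molecules]


def read_sdf(path: str | Path, activity_tag: str = "activity") -> MoleculeSet:
    """Read an MDL V2000 SDF with 3D coordinates into a MoleculeSet.

    The activity tag is parsed as float when present; molecules lacking it are
    kept with ``activity=None`` (prediction sets).  Unparsable records and
    non-numeric activity values raise with the offending record identified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"no records in SDF file {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    molecules: list[Molecule] = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ValueError(f"unparsable SDF record at index {i} in {path}")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        if not name.strip():
            name = f"mol_{i}"
        activity: float | None = None
        if rdmol.HasProp(activity_tag):
            raw = rdmol.GetProp(activity_tag)
            try:
                activity = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"activity tag {activity_tag!r} of molecule {name!r} "
                    f"is not numeric: {raw!r}"
                ) from exc
        if rdmol.GetNumConformers() == 0:
            raise ValueError(f"SDF record {name!r} carries no coordinates")
        coords = rdmol.GetConformer().GetPositions()
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in molecule {name!r}")
        molecules.append(Molecule(name=name, rdmol=rdmol, activity=activity))
    if not molecules:
        raise ValueError(f"no records in SDF file {path}")
    return MoleculeSet(molecules)


def read_smiles_table(path: str | Path) -> MoleculeSet:
    """Read a name,smiles,activity CSV into a topology-only MoleculeSet.

    A header row is optional.  The returned molecules have no conformers and
    are flagged ``needs_embedding`` for the alignment stage.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns name,smiles[,activity]")
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if "smiles" in first or "name" in first:
        df = df.iloc[1:].reset_index(drop=True)
    molecules: list[Molecule] = []
    for row_idx, row in df.iterrows():
        name = str(row[0]).strip()
        smiles = str(row[1]).strip()
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise ValueError(f"invalid SMILES at row {row_idx + 1}: {smiles!r}")
        activity = None
        if df.shape[1] > 2 and pd.notna(row[2]) and str(row[2]).strip():
            try:
                activity = float(row[2])
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric activity at row {row_idx + 1}: {row[2]!r}"
                ) from exc
        rdmol.SetProp("_Name", name)
        molecules.append(
            Molecule(name=name, rdmol=rdmol, activity=activity, needs_embedding=True)
        )
    if not molecules:
        raise ValueError(f"no rows in SMILES table {path}")
    return MoleculeSet(molecules)


def read_smarts_file(path: str | Path) -> tuple[list[str], list[str]]:
    """Parse a role-prefixed SMARTS override file.

    One pattern per line, ``donor <SMARTS>`` or ``acceptor <SMARTS>``; blank
    lines and ``#`` comments ignored.
    """
    donors: list[str] = []
    acceptors: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2 or parts[0] not in ("donor", "acceptor"):
            raise ValueError(f"{path}:{lineno}: expected 'donor|acceptor <SMARTS>'")
        role, smarts = parts
        if Chem.MolFromSmarts(smarts) is None:
            raise ValueError(f"{path}:{lineno}: invalid SMARTS {smarts!r}")
        (donors if role == "donor" else acceptors).append(smarts)
    return donors, acceptors


_HYB_MAP = {
    Chem.HybridizationType.SP: Hybridization.SP,
    Chem.HybridizationType.SP2: Hybridization.SP2,
    Chem.HybridizationType.SP3: Hybridization.SP3,
}


def _match_atoms(rdmol: Chem.Mol, patterns: Iterable[str]) -> set[int]:
    hits: set[int] = set()
    for smarts in patterns:
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"invalid SMARTS pattern {smarts!r}")
        for match in rdmol.GetSubstructMatches(query):
            hits.add(match[0])
    return hits


def annotate_atoms(
    mol: Molecule,
    add_hs: bool = True,
    donor_smarts: Sequence[str] | None = None,
    acceptor_smarts: Sequence[str] | None = None,
) -> Molecule:
    """Return a copy of ``mol`` with every atom annotated for field building.

    Explicit hydrogens are added (with coordinates) by default since both the
    Gasteiger charge model and H-bond donor geometry need them.
    """
    if not mol.has_conformer():
        raise ValueError(f"molecule {mol.name!r} has no 3D coordinates to annotate")
    rdmol = Chem.Mol(mol.rdmol)
    if add_hs:
        rdmol = Chem.AddHs(rdmol, addCoords=True)
    Chem.SanitizeMol(rdmol)

    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() not in VDW_RADII:
            raise ValueError(
                f"unknown element {atom.GetSymbol()!r} in molecule {mol.name!r}"
            )

    AllChem.ComputeGasteigerCharges(rdmol)
    charges = [a.GetDoubleProp("_GasteigerCharge") for a in rdmol.GetAtoms()]
    if not all(math.isfinite(c) for c in charges):
        raise ValueError(
            f"Gasteiger charge computation failed for molecule {mol.name!r}"
        )
    crippen = rdMolDescriptors._CalcCrippenContribs(rdmol)

    donors = _match_atoms(rdmol, donor_smarts or DEFAULT_DONOR_SMARTS)
    acceptors = _match_atoms(rdmol, acceptor_smarts or DEFAULT_ACCEPTOR_SMARTS)

    conf = rdmol.GetConformer()
    pos = np.array(conf.GetPositions(), dtype=float)
    records: list[AtomRecord] = []
    for atom in rdmol.GetAtoms():
        i = atom.GetIdx()
        h_pos = [
            pos[n.GetIdx()].copy()
            for n in atom.GetNeighbors()
            if n.GetAtomicNum() == 1
        ]
        records.append(
            AtomRecord(
                index=i,
                element=atom.GetSymbol(),
                coords=pos[i].copy(),
                vdw_radius=VDW_RADII[atom.GetSymbol()],
                gasteiger_charge=charges[i],
                crippen_logp=crippen[i][0],
                is_donor=i in donors,
                is_acceptor=i in acceptors,
                hybridization=_HYB_MAP.get(atom.GetHybridization(), Hybridization.OTHER),
                attached_h_positions=h_pos,
            )
        )
    return replace(mol, rdmol=rdmol, atoms=records)


def annotate_set(mset: MoleculeSet, **kwargs) -> MoleculeSet:
    return MoleculeSet([annotate_atoms(m, **kwargs) for m in mset], role=mset.role)


def write_sdf(
    mset: MoleculeSet, path: str | Path, activity_tag: str = "activity"
) -> Path:
    """Write a MoleculeSet as MDL V2000 SDF; activity tag omitted when absent."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mset:
            if not mol.has_conformer():
                raise ValueError(f"molecule {mol.name!r} has no 3D coordinates")
            rdmol = Chem.Mol(mol.rdmol)
            rdmol.SetProp("_Name", mol.name)
            if mol.activity is not None:
                rdmol.SetProp(activity_tag, repr(float(mol.activity)))
            elif rdmol.HasProp(activity_tag):
                rdmol.ClearProp(activity_tag)
            writer.write(rdmol)
    finally:
        writer.close()
    return path
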