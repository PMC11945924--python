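"""Common-frame alignment of unaligned molecules via their maximum common
substructure (MCS).

The first molecule (or a user-named one) is the template: it is embedded in 3D
from a fixed random seed and force-field minimized.  Every other molecule is
embedded with its MCS atoms restrained to the template's MCS coordinates,
minimized, and rigidly refit onto the template core; the residual core RMSD is
reported per molecule.  All randomness flows from the single seed, so repeated
runs are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS
from rdkit.Geometry import Point3D

from .chemio import Molecule, MoleculeSet

__all__ = ["AlignmentResult", "find_mcs", "align_set"]

MIN_CORE_ATOMS = 3


@dataclass
class AlignmentResult:
    aligned: MoleculeSet
    template_name: str
    core_rmsd: list[float]
    mcs_smarts: str
    warnings: list[str] = field(default_factory=list)


def find_mcs(mset: MoleculeSet, strict: bool = True, timeout: int = 30) -> str:
    """SMARTS of the maximum common substructure over all molecules in the set.

    ``strict`` compares elements and bond orders exactly (rings required to
    match rings); relaxing it tolerates bond-order differences.
    """
    if len(mset) < 2:
        raise ValueError("MCS search needs at least 2 molecules")
    params = rdFMCS.MCSParameters()
    params.Timeout = timeout
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = (
        rdFMCS.BondCompare.CompareOrder if strict else rdFMCS.BondCompare.CompareAny
    )
    params.BondCompareParameters.RingMatchesRingOnly = True
    result = rdFMCS.FindMCS([m.rdmol for m in mset], params)
    if result.numAtoms < MIN_CORE_ATOMS:
        raise ValueError(
            f"alignment core too small: MCS has {result.numAtoms} atoms "
            f"(need >= {MIN_CORE_ATOMS})"
        )
    return result.smartsString


def _minimize(rdmol: Chem.Mol, max_rounds: int = 10, max_iters: int = 200,
              energy_tol: float = 1e-6) -> bool:
    """Iterated UFF minimization until the energy change falls below tolerance.

    Returns True on convergence, False if the round budget was exhausted.
    """
    ff = AllChem.UFFGetMoleculeForceField(rdmol)
    if ff is None:
        return True  # no parametrizable interactions (e.g. single atom)
    prev = ff.CalcEnergy()
    for _ in range(max_rounds):
        not_converged = AllChem.UFFOptimizeMolecule(rdmol, maxIters=max_iters)
        energy = AllChem.UFFGetMoleculeForceField(rdmol).CalcEnergy()
        if not_converged == 0 or abs(prev - energy) < energy_tol:
            return True
        prev = energy
    return False


def align_set(
    mset: MoleculeSet,
    seed: int,
    template: str | None = None,
    strict_mcs: bool = True,
) -> AlignmentResult:
    """Embed and align a molecule set onto its shared MCS core.

    Parameters
    ----------
    mset : molecules from SMILES (no conformers) or with conformers to re-embed.
    seed : random seed for every 3D embedding, fixed for reproducibility.
    template : optional molecule name to use as the template; default is the
        first molecule in input order.
    """
    if len(mset) == 0:
        raise ValueError("empty molecule set")
    order = list(mset.molecules)
    if template is not None:
        idx = next((i for i, m in enumerate(order) if m.name == template), None)
        if idx is None:
            raise ValueError(f"template molecule {template!r} not in set")
        order = [order[idx]] + order[:idx] + order[idx + 1:]

    notes: list[str] = []

    def _embedded(mol: Molecule, coord_map=None) -> Chem.Mol:
        rdmol = Chem.AddHs(Chem.Mol(mol.rdmol))
        kwargs = dict(randomSeed=seed, useRandomCoords=False)
        if coord_map:
            kwargs["coordMap"] = coord_map
        if AllChem.EmbedMolecule(rdmol, **kwargs) != 0:
            raise ValueError(f"3D embedding failed for molecule {mol.name!r}")
        if not _minimize(rdmol):
            notes.append(f"minimization did not converge for {mol.name!r}")
            warnings.warn(f"minimization did not converge for {mol.name!r}")
        return rdmol

    tmpl_rd = _embedded(order[0])
    aligned = [replace(order[0], rdmol=tmpl_rd, needs_embedding=False, atoms=[])]
    rmsds = [0.0]

    if len(order) > 1:
        mcs_smarts = find_mcs(mset, strict=strict_mcs)
        query = Chem.MolFromSmarts(mcs_smarts)
        tmpl_match = tmpl_rd.GetSubstructMatch(query)
        if not tmpl_match:
            raise ValueError("template does not match its own MCS")
        tmpl_conf = tmpl_rd.GetConformer()
        for mol in order[1:]:
            probe = Chem.AddHs(Chem.Mol(mol.rdmol))
            match = probe.GetSubstructMatch(query)
            if not match:
                raise ValueError(f"molecule {mol.name!r} does not match the MCS")
            coord_map = {
                probe_idx: Point3D(*tmpl_conf.GetAtomPosition(t_idx))
                for probe_idx, t_idx in zip(match, tmpl_match)
            }
            rdmol = _embedded(mol, coord_map=coord_map)
            atom_map = list(zip(match, tmpl_match))
            rmsd = AllChem.AlignMol(rdmol, tmpl_rd, atomMap=atom_map)
            aligned.append(replace(mol, rdmol=rdmol, needs_embedding=False, atoms=[]))
            rmsds.append(float(rmsd))
    else:
        mcs_smarts = Chem.MolToSmarts(Chem.RemoveHs(tmpl_rd))

    return AlignmentResult(
        aligned=MoleculeSet(aligned, role=mset.role),
        template_name=order[0].name,
        core_rmsd=rmsds,
        mcs_smarts=mcs_smarts,
        warnings=notes,
    )
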