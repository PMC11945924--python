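"""Gaussian similarity fields: sources, pseudoatom geometry, accumulation."""

import numpy as np
import pytest

from comsia.chemio import AtomRecord, Molecule, MoleculeSet
from comsia.fields import (
    FieldConfig,
    GaussianSource,
    acceptor_pseudoatoms,
    compute_all_fields,
    donor_pseudoatoms,
    electrostatic_sources,
    gaussian_accumulate,
    hydrophobic_sources,
    steric_sources,
)
from comsia.grid import GridSpec, build_grid, grid_points

RAW = FieldConfig(snap=False)


def brute_force(sources, points, alpha):
    """Naive per-point / per-source triple loop; the independent oracle."""
    out = np.zeros(len(points))
    for pi, p in enumerate(points):
        total = 0.0
        for s in sources:
            d2 = sum((p[c] - s.center[c]) ** 2 for c in range(3))
            total += s.weight * np.exp(-alpha * d2)
        out[pi] = total
    return out


class TestGaussianAccumulate:
    def test_value_at_own_lattice_point_is_weight(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(3, 3, 3), padding=0.0)
        src = [GaussianSource(center=np.array([1.0, 1.0, 1.0]), weight=2.5)]
        vals = gaussian_accumulate(src, grid, alpha=0.3)
        at_source = vals[grid.flat_index(1, 1, 1)]
        assert at_source == pytest.approx(2.5, rel=1e-9)
        assert np.all(vals <= at_source + 1e-12)

    def test_unit_source_at_unit_distance(self):
        src = [GaussianSource(center=np.zeros(3), weight=1.0)]
        val = gaussian_accumulate(src, np.array([[1.0, 0.0, 0.0]]), alpha=0.3)
        assert val[0] == pytest.approx(np.exp(-0.3), abs=1e-12)

    def test_additivity(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(4, 4, 4), padding=0.0)
        src = [GaussianSource(center=np.array([1.2, 0.3, 2.0]), weight=1.7)]
        one = gaussian_accumulate(src, grid, alpha=0.3)
        two = gaussian_accumulate(src * 2, grid, alpha=0.3)
        assert np.allclose(two, 2 * one, atol=1e-12)

    def test_monotone_decay_from_single_source(self):
        src = [GaussianSource(center=np.zeros(3), weight=1.0)]
        dists = np.linspace(0, 5, 40)
        pts = np.column_stack([dists, np.zeros(40), np.zeros(40)])
        vals = gaussian_accumulate(src, pts, alpha=0.3)
        assert np.all(np.diff(vals) < 0)

    def test_larger_alpha_gives_smaller_field_off_source(self):
        src = [GaussianSource(center=np.zeros(3), weight=1.0)]
        pt = np.array([[1.3, 0.4, -0.2]])
        assert gaussian_accumulate(src, pt, 0.6)[0] < gaussian_accumulate(src, pt, 0.3)[0]

    def test_matches_brute_force_oracle(self, ethanol):
        grid = GridSpec(origin=(-3.0, -3.0, -3.0), spacing=0.75, dims=(9, 9, 9), padding=0.0)
        pts = grid_points(grid)
        sources = steric_sources(ethanol, RAW)
        fast = gaussian_accumulate(sources, pts, alpha=0.3)
        slow = brute_force(sources, pts, alpha=0.3)
        assert np.allclose(fast, slow, atol=1e-10)


class TestAtomSources:
    def test_steric_weight_is_radius_cubed(self, methane):
        for src, atom in zip(steric_sources(methane, RAW), methane.atoms):
            assert src.weight == pytest.approx(atom.vdw_radius ** 3)

    def test_source_count_matches_atom_count(self, ethanol):
        assert len(steric_sources(ethanol, RAW)) == len(ethanol.atoms)

    def test_hydrogen_suppression(self, ethanol):
        cfg = FieldConfig(snap=False, include_hydrogens=False)
        heavy = [a for a in ethanol.atoms if a.element != "H"]
        assert len(steric_sources(ethanol, cfg)) == len(heavy)

    def test_electrostatic_weights_conserve_charge(self, ethanol):
        total = sum(s.weight for s in electrostatic_sources(ethanol, RAW))
        assert abs(total) < 1e-3

    def test_carbonyl_charge_signs(self, formaldehyde):
        srcs = electrostatic_sources(formaldehyde, RAW)
        o = next(s for s, a in zip(srcs, formaldehyde.atoms) if a.element == "O")
        c = next(s for s, a in zip(srcs, formaldehyde.atoms) if a.element == "C")
        assert o.weight < 0 < c.weight

    def test_hydrophobic_weights(self, butane, ethanol):
        carbons = [
            s.weight
            for s, a in zip(hydrophobic_sources(butane, RAW), butane.atoms)
            if a.element == "C"
        ]
        assert all(w > 0 for w in carbons)
        o_weight = next(
            s.weight
            for s, a in zip(hydrophobic_sources(ethanol, RAW), ethanol.atoms)
            if a.element == "O"
        )
        assert o_weight < 0


class TestDonorPseudoatoms:
    def test_water_two_sites_at_fixed_distance(self, water):
        cfg = FieldConfig(snap=False)
        sites = donor_pseudoatoms(water, cfg)
        assert len(sites) == 2
        o = next(a for a in water.atoms if a.element == "O")
        for s in sites:
            assert np.linalg.norm(s.center - o.coords) == pytest.approx(1.9, abs=1e-6)
            assert s.weight == 1.0

    def test_methane_has_no_donor_sites(self, methane):
        assert donor_pseudoatoms(methane, RAW) == []

    def test_site_on_oh_ray(self, ethanol):
        cfg = FieldConfig(snap=False)
        o = next(a for a in ethanol.atoms if a.element == "O")
        (site,) = donor_pseudoatoms(ethanol, cfg)
        ray = (o.attached_h_positions[0] - o.coords)
        ray /= np.linalg.norm(ray)
        offset = site.center - o.coords
        assert np.allclose(offset / np.linalg.norm(offset), ray, atol=1e-9)

    def test_clash_with_neighboring_atom_drops_site(self):
        # donor O at origin with H pointing at a big blocking atom 1.9 Å away
        o = AtomRecord(0, "O", np.zeros(3), vdw_radius=1.52, gasteiger_charge=-0.4,
                       crippen_logp=-0.2, is_donor=True,
                       attached_h_positions=[np.array([0.96, 0.0, 0.0])])
        h = AtomRecord(1, "H", np.array([0.96, 0.0, 0.0]), vdw_radius=1.2,
                       gasteiger_charge=0.2, crippen_logp=0.1)
        blocker = AtomRecord(2, "S", np.array([1.9, 0.0, 0.0]), vdw_radius=1.8,
                             gasteiger_charge=0.0, crippen_logp=0.3)
        crowded = Molecule(name="crowded", rdmol=None, atoms=[o, h, blocker])
        assert donor_pseudoatoms(crowded, RAW) == []
        # removing the blocker restores the site
        free = Molecule(name="free", rdmol=None, atoms=[o, h])
        assert len(donor_pseudoatoms(free, RAW)) == 1

    def test_donor_without_h_warns_and_skips(self):
        o = AtomRecord(0, "O", np.zeros(3), vdw_radius=1.52, gasteiger_charge=-0.4,
                       crippen_logp=-0.2, is_donor=True, attached_h_positions=[])
        mol = Molecule(name="bare", rdmol=None, atoms=[o])
        notes: list[str] = []
        with pytest.warns(UserWarning, match="no locatable H"):
            assert donor_pseudoatoms(mol, RAW, collect=notes) == []
        assert notes


class TestAcceptorPseudoatoms:
    def test_carbonyl_oxygen_two_inplane_sites(self, formaldehyde):
        cfg = FieldConfig(snap=False)
        sites = acceptor_pseudoatoms(formaldehyde, cfg)
        assert len(sites) == 2
        o = next(a for a in formaldehyde.atoms if a.element == "O")
        c = next(a for a in formaldehyde.atoms if a.element == "C")
        bond = (o.coords - c.coords) / np.linalg.norm(o.coords - c.coords)
        plane_normal = None
        for s in sites:
            offset = s.center - o.coords
            assert np.linalg.norm(offset) == pytest.approx(1.9, abs=1e-6)
            direction = offset / np.linalg.norm(offset)
            # 120 degrees from the C->O bond direction
            angle = np.degrees(np.arccos(np.clip(np.dot(direction, bond), -1, 1)))
            assert angle == pytest.approx(60.0, abs=1.0)
            # in the molecular plane
            h_pos = [a.coords for a in formaldehyde.atoms if a.element == "H"]
            normal = np.cross(h_pos[0] - c.coords, h_pos[1] - c.coords)
            normal /= np.linalg.norm(normal)
            assert abs(np.dot(direction, normal)) < 1e-6

    def test_ether_oxygen_two_tetrahedral_sites(self, dimethyl_ether):
        cfg = FieldConfig(snap=False)
        sites = acceptor_pseudoatoms(dimethyl_ether, cfg)
        assert len(sites) == 2
        o = next(a for a in dimethyl_ether.atoms if a.element == "O")
        dirs = []
        for s in sites:
            offset = s.center - o.coords
            assert np.linalg.norm(offset) == pytest.approx(1.9, abs=1e-6)
            dirs.append(offset / np.linalg.norm(offset))
        lp_angle = np.degrees(np.arccos(np.clip(np.dot(dirs[0], dirs[1]), -1, 1)))
        assert lp_angle == pytest.approx(109.47, abs=2.0)

    def test_non_acceptor_molecule_yields_nothing(self, methane):
        assert acceptor_pseudoatoms(methane, RAW) == []


class TestComputeAllFields:
    def test_tensor_shape(self, ethanol):
        mset = MoleculeSet([ethanol])
        grid = GridSpec(origin=(-4, -4, -4), spacing=1.0, dims=(9, 9, 9), padding=4.0)
        tensor = compute_all_fields(mset, grid, FieldConfig(fields_enabled="SEH"))
        assert tensor.values.shape == (1, 3, 729)
        assert tensor.field_names == ("S", "E", "H")

    def test_all_five_layers_nontrivial(self, ethanol):
        mset = MoleculeSet([ethanol])
        grid = build_grid(mset)
        tensor = compute_all_fields(mset, grid, FieldConfig(fields_enabled="SEHAD"))
        for fi in range(5):
            assert tensor.values[0, fi].std() > 0

    def test_translation_equivariance(self, ethanol):
        import copy
        mset = MoleculeSet([ethanol])
        grid = build_grid(mset, spacing=1.0, padding=4.0)
        base = compute_all_fields(mset, grid, FieldConfig())
        shift = np.array([2.0, -1.0, 3.0])
        moved = copy.deepcopy(ethanol)
        conf = moved.rdmol.GetConformer()
        for i in range(moved.rdmol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, tuple(np.array([p.x, p.y, p.z]) + shift))
        for a in moved.atoms:
            a.coords = a.coords + shift
            a.attached_h_positions = [h + shift for h in a.attached_h_positions]
        moved_grid = GridSpec(
            origin=tuple(np.asarray(grid.origin) + shift),
            spacing=grid.spacing, dims=grid.dims, padding=grid.padding,
        )
        shifted = compute_all_fields(MoleculeSet([moved]), moved_grid, FieldConfig())
        assert np.allclose(shifted.values, base.values, atol=1e-9)

    def test_pseudoatom_parent_distance_and_clash_invariants(self, small_fixture):
        train, _, _ = small_fixture
        cfg = FieldConfig(snap=False)
        for mol in train:
            for builder, flag in ((donor_pseudoatoms, "is_donor"),
                                  (acceptor_pseudoatoms, "is_acceptor")):
                parents = [a for a in mol.atoms if getattr(a, flag)]
                for site in builder(mol, cfg):
                    dists = [np.linalg.norm(site.center - p.coords) for p in parents]
                    assert any(abs(d - 1.9) < 1e-6 for d in dists)
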