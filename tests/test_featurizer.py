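"""Atom typing, chemical property perception and voxel-grid construction."""

import logging

import numpy as np
import pytest
from rdkit import Chem

from pocketseg import (
    AtomRecord,
    CleanStructure,
    FeaturizationError,
    GridConfig,
    MolecularContext,
    classify_atom_type,
    compute_atom_features,
    protein_center,
    voxelize,
    voxelize_label,
)
from pocketseg.featurizer import CHANNEL_NAMES, world_to_voxel
from pocketseg.grids import load_grid, save_grid


def atom(serial, xyz, element="C", z=6):
    return AtomRecord(
        element_symbol=element,
        atomic_number=z,
        coords=np.asarray(xyz, float),
        residue_name="UNK",
        chain_id="A",
        is_hetero=False,
        serial=serial,
        atom_name=element,
        res_seq=serial,
    )


class TestClassifyAtomType:
    @pytest.mark.parametrize(
        "z,channel",
        [
            (5, 0),  # B
            (6, 1),  # C
            (7, 2),  # N
            (8, 3),  # O
            (15, 4),  # P
            (16, 5),  # S
            (34, 6),  # Se
            (9, 7), (17, 7), (35, 7), (53, 7),  # halogens
            (26, 8),  # Fe, inside the 19-32 metal range
            (11, 8), (30, 8), (42, 8), (78, 8), (92, 8),  # more metals
            (1, None),  # hydrogen maps to no channel
            (2, None), (10, None),  # noble gases
        ],
    )
    def test_mapping(self, z, channel):
        assert classify_atom_type(z) == channel

    def test_rules_mutually_exclusive(self):
        for z in range(1, 105):
            hits = []
            if z in (5, 6, 7, 8, 15, 16, 34):
                hits.append("direct")
            if z in (9, 17, 35, 53):
                hits.append("halogen")
            from pocketseg.featurizer import _METALS

            if z in _METALS:
                hits.append("metal")
            assert len(hits) <= 1, f"Z={z} claimed by {hits}"


class TestGridConfig:
    def test_default_spacing_is_two_angstrom(self):
        cfg = GridConfig()
        assert cfg.side == 36 and cfg.span == 70.0
        assert cfg.spacing == pytest.approx(2.0)

    def test_invalid_configs_raise(self):
        with pytest.raises(FeaturizationError):
            GridConfig(side=1)
        with pytest.raises(FeaturizationError):
            GridConfig(span=-1.0)


class TestProteinCenter:
    def test_midpoint(self):
        s = CleanStructure(atoms=[atom(1, (0, 0, 0)), atom(2, (2, 0, 0))])
        np.testing.assert_allclose(protein_center(s), [1, 0, 0])

    def test_single_atom(self):
        s = CleanStructure(atoms=[atom(1, (5, 5, 5))])
        np.testing.assert_allclose(protein_center(s), [5, 5, 5])

    def test_symmetric_corners(self):
        corners = [(1, 1, 1), (-1, 1, -1), (1, -1, -1), (-1, -1, 1)]
        s = CleanStructure(atoms=[atom(i + 1, c) for i, c in enumerate(corners)])
        np.testing.assert_allclose(protein_center(s), [0, 0, 0], atol=1e-12)


class TestPerception:
    def test_benzene_carbon_aromatic_ring(self):
        ctx = MolecularContext.from_mol(Chem.MolFromSmiles("c1ccccc1"))
        feats = compute_atom_features(atom(1, (0, 0, 0)), ctx)
        props = dict(zip(CHANNEL_NAMES[9:], feats.properties))
        assert props["aromatic"] == 1.0
        assert props["ring"] == 1.0
        assert feats.type_channel == 1

    def test_amide_oxygen_acceptor_not_donor(self):
        # N-methylacetamide: index 2 is the carbonyl oxygen, index 3 the N-H
        ctx = MolecularContext.from_mol(Chem.MolFromSmiles("CC(=O)NC"))
        o_feats = compute_atom_features(atom(3, (0, 0, 0), "O", 8), ctx)
        n_feats = compute_atom_features(atom(4, (0, 0, 0), "N", 7), ctx)
        props_o = dict(zip(CHANNEL_NAMES[9:], o_feats.properties))
        props_n = dict(zip(CHANNEL_NAMES[9:], n_feats.properties))
        assert props_o["acceptor"] == 1.0 and props_o["donor"] == 0.0
        assert props_n["donor"] == 1.0

    def test_isolated_atom_has_no_neighbors(self):
        s = CleanStructure(atoms=[atom(1, (0, 0, 0))], source_id="lone")
        ctx = MolecularContext.from_structure(s)
        feats = compute_atom_features(s.atoms[0], ctx)
        props = dict(zip(CHANNEL_NAMES[9:], feats.properties))
        assert props["heteroatoms"] == 0.0
        assert props["non_hydrogens"] == 0.0

    def test_unknown_serial_raises_named_error(self):
        ctx = MolecularContext.from_mol(Chem.MolFromSmiles("C"))
        with pytest.raises(FeaturizationError, match="99"):
            compute_atom_features(atom(99, (0, 0, 0)), ctx)


class TestVoxelize:
    def test_single_carbon_at_center(self):
        s = CleanStructure(atoms=[atom(1, (10.0, -3.0, 7.0))], source_id="one")
        grid = voxelize(s, GridConfig())
        nz = np.argwhere(grid.values.sum(axis=-1) > 0)
        assert len(nz) == 1
        # the centre of a 36-voxel grid sits between centres 17 and 18;
        # the halfway tie resolves to the lower index
        assert tuple(nz[0]) == (17, 17, 17)
        assert grid.values[17, 17, 17, 1] == 1.0  # carbon channel

    def test_output_shape_default(self, toy_complex):
        grid = voxelize(toy_complex.structure, GridConfig())
        assert grid.values.shape == (36, 36, 36, 18)

    def test_atom_outside_grid_discarded(self, caplog):
        s = CleanStructure(
            atoms=[atom(1, (0, 0, 0)), atom(2, (200.0, 0, 0))], source_id="far"
        )
        with caplog.at_level(logging.WARNING):
            grid = voxelize(s, GridConfig())
        assert "discarded" in caplog.text
        # center is at (100,0,0); both atoms are 100 A away on x: all outside
        assert grid.values.sum() == 0.0

    def test_type_channel_sum_counts_atoms(self, toy_complex):
        grid = voxelize(toy_complex.structure, GridConfig())
        counts = {1: 0, 2: 0, 3: 0, 4: 0, 5: 0}
        for a in toy_complex.structure.atoms:
            ch = classify_atom_type(a.atomic_number)
            counts[ch] += 1
        for ch, n in counts.items():
            assert grid.values[..., ch].sum() == pytest.approx(n)

    def test_translation_equivariance(self, toy_complex):
        s = toy_complex.structure
        shift = np.array([13.7, -4.2, 8.9])
        moved = CleanStructure(
            atoms=[
                AtomRecord(
                    a.element_symbol, a.atomic_number, a.coords + shift,
                    a.residue_name, a.chain_id, a.is_hetero, a.serial,
                    a.atom_name, a.res_seq,
                )
                for a in s.atoms
            ],
            source_id=s.source_id,
        )
        g1 = voxelize(s, GridConfig())
        g2 = voxelize(moved, GridConfig())
        np.testing.assert_array_equal(g1.values, g2.values)

    def test_property_voxels_have_atoms(self, toy_complex):
        grid = voxelize(toy_complex.structure, GridConfig())
        prop_active = np.abs(grid.values[..., 9:]).sum(axis=-1) > 0
        type_active = grid.values[..., :9].sum(axis=-1) > 0
        assert np.all(type_active[prop_active])


class TestVoxelizeLabel:
    def test_empty_points_all_zero(self):
        lab = voxelize_label(np.empty((0, 3)), GridConfig(), center=np.zeros(3))
        assert lab.values.sum() == 0

    def test_single_center_point(self):
        lab = voxelize_label(np.zeros((1, 3)), GridConfig(), center=np.zeros(3))
        assert lab.values.sum() == 1
        assert lab.values[17, 17, 17] == 1

    def test_eight_point_cube(self):
        cfg = GridConfig()
        center = np.zeros(3)
        origin = cfg.origin_for_center(center)
        # points exactly on 8 neighbouring voxel centres
        base = origin + cfg.spacing * 17
        pts = [base + cfg.spacing * np.array(o) for o in np.ndindex(2, 2, 2)]
        lab = voxelize_label(np.array(pts), cfg, center=center)
        assert lab.values.sum() == 8

    def test_shares_geometry_with_feature_grid(self, toy_complex):
        cfg = GridConfig()
        grid = voxelize(toy_complex.structure, cfg)
        center = protein_center(toy_complex.structure)
        lab = voxelize_label(toy_complex.truth_points, cfg, center=center)
        np.testing.assert_array_equal(lab.origin, grid.origin)
        assert lab.spacing == grid.spacing


class TestAssignment:
    def test_round_trip_voxel_center(self):
        origin = np.array([-35.0, -35.0, -35.0])
        for idx in [(0, 0, 0), (17, 3, 35), (35, 35, 35)]:
            coord = origin + 2.0 * np.array(idx)
            assert tuple(world_to_voxel(coord, origin, 2.0)) == idx

    def test_halfway_tie_goes_to_lower_index(self):
        origin = np.zeros(3)
        tie = np.array([1.0, 0.0, 0.0])  # halfway between centres 0 and 1 at spacing 2
        assert tuple(world_to_voxel(tie, origin, 2.0)) == (0, 0, 0)


class TestGridArchive:
    def test_bit_exact_round_trip(self, tmp_path, toy_complex):
        grid = voxelize(toy_complex.structure, GridConfig())
        path = tmp_path / "grid.npz"
        save_grid(path, grid)
        again = load_grid(path)
        np.testing.assert_array_equal(again.values, grid.values)
        np.testing.assert_array_equal(again.origin, grid.origin)
        assert again.spacing == grid.spacing
        assert again.channel_names == tuple(CHANNEL_NAMES)
        assert again.source_id == grid.source_id
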