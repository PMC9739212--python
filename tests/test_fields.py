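"""Probe-energy and similarity fields, grid construction, block assembly."""

import numpy as np
import pytest

from qsarfield.dataset import Atom, Molecule
from qsarfield.fields import (
    COULOMB_CONSTANT,
    ENERGY_CAP,
    GridSpec,
    ProbeSpec,
    apply_block,
    build_block,
    comfa_fields,
    comsia_fields,
    make_grid,
)


def _atom_mol(element="C", pos=(0, 0, 0), **kw):
    return Molecule("m", [Atom(element, np.array(pos, dtype=float), **kw)])


def _single_node_grid(pos) -> GridSpec:
    return GridSpec(origin=tuple(float(v) for v in pos), spacing=1.0, dims=(1, 1, 1))


class TestGrid:
    def test_single_atom_box(self):
        grid = make_grid([_atom_mol()], spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert grid.n_nodes == 125
        nodes = grid.nodes()
        assert nodes.min() == -4.0 and nodes.max() == 4.0

    def test_every_atom_has_clearance(self, rng):
        coords = rng.uniform(-3, 7, (12, 3))
        mol = Molecule("m", [Atom("C", c) for c in coords])
        grid = make_grid([mol], spacing=2.0, margin=4.0)
        lo = np.asarray(grid.origin)
        hi = lo + grid.spacing * (np.asarray(grid.dims) - 1)
        assert np.all(coords >= lo + (4.0 - 2.0) - 1e-9)
        assert np.all(coords <= hi - (4.0 - 2.0) + 1e-9)

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            make_grid([_atom_mol()], spacing=0.0)

    def test_x_fastest_linearization(self):
        grid = GridSpec((0.0, 0.0, 0.0), 1.0, (3, 2, 2))
        nodes = grid.nodes()
        assert np.allclose(nodes[1], [1, 0, 0])  # x moves first
        assert np.allclose(nodes[3], [0, 1, 0])
        assert np.allclose(nodes[6], [0, 0, 1])
        assert grid.nearest_node((2.2, 1.1, 0.4)) == 2 + 3 * 1


class TestProbeEnergies:
    def test_distant_node_on_chargeless_molecule(self):
        mol = _atom_mol(partial_charge=0.0)
        grid = _single_node_grid((12.0, 0, 0))
        steric, elec = comfa_fields(mol, grid)
        assert abs(steric[0]) < 1e-3
        assert elec[0] == 0.0

    def test_coincident_node_clamped(self):
        mol = _atom_mol(partial_charge=0.0)
        grid = _single_node_grid((0, 0, 0))
        steric, elec = comfa_fields(mol, grid)
        assert steric[0] == ENERGY_CAP
        assert np.isnan(elec[0])  # flagged for column-mean substitution

    def test_electrostatic_point_value(self):
        mol = _atom_mol(partial_charge=1.0)
        grid = _single_node_grid((4.0, 0, 0))
        _, elec = comfa_fields(mol, grid)
        assert elec[0] == pytest.approx(COULOMB_CONSTANT / 16.0, abs=1e-6)

    def test_electrostatic_cap(self):
        mol = _atom_mol(partial_charge=-1.0)
        grid = _single_node_grid((2.4, 0, 0))  # outside steric clash, close enough
        steric, elec = comfa_fields(mol, grid)
        assert steric[0] < ENERGY_CAP
        assert elec[0] == -ENERGY_CAP


class TestSimilarityFields:
    def test_zero_distance(self):
        mol = _atom_mol(hydrophobic_w=1.0)
        vals = comsia_fields(mol, _single_node_grid((0, 0, 0)), kinds=("hydrophobic",))
        assert vals["hydrophobic"][0] == pytest.approx(-1.0, abs=1e-12)

    def test_one_angstrom(self):
        mol = _atom_mol(hydrophobic_w=1.0)
        vals = comsia_fields(mol, _single_node_grid((1.0, 0, 0)), kinds=("hydrophobic",))
        assert vals["hydrophobic"][0] == pytest.approx(-np.exp(-0.3), abs=1e-6)

    def test_additivity(self):
        a = _atom_mol(hydrophobic_w=0.7, pos=(0, 0, 0))
        b = _atom_mol(hydrophobic_w=0.4, pos=(1.2, 0.5, 0))
        both = Molecule("m", a.atoms + b.atoms)
        grid = _single_node_grid((0.6, 0.2, 0.9))
        va = comsia_fields(a, grid, kinds=("hydrophobic",))["hydrophobic"]
        vb = comsia_fields(b, grid, kinds=("hydrophobic",))["hydrophobic"]
        vab = comsia_fields(both, grid, kinds=("hydrophobic",))["hydrophobic"]
        assert vab[0] == pytest.approx(va[0] + vb[0], abs=1e-12)

    def test_alpha_zero_limit_totals_weights(self, rng):
        coords = rng.uniform(-2, 2, (5, 3))
        weights = rng.uniform(0, 1, 5)
        mol = Molecule("m", [Atom("C", c, hydrophobic_w=w) for c, w in zip(coords, weights)])
        probe = ProbeSpec(attenuation_alpha=1e-12)
        vals = comsia_fields(mol, _single_node_grid((0.3, 0.1, -0.4)), probe, ("hydrophobic",))
        assert vals["hydrophobic"][0] == pytest.approx(-weights.sum(), abs=1e-9)

    def test_translation_equivariance(self, rng):
        coords = rng.uniform(-2, 2, (4, 3))
        mol = Molecule("m", [Atom("C", c, hydrophobic_w=0.5, partial_charge=0.1) for c in coords])
        grid = make_grid([mol], 2.0, 3.0)
        shift = np.array([3.7, -1.2, 0.9])
        mol2 = mol.with_coords(coords + shift)
        grid2 = GridSpec(tuple(np.asarray(grid.origin) + shift), grid.spacing, grid.dims)
        for kind in ("steric", "hydrophobic"):
            v1 = comsia_fields(mol, grid, kinds=(kind,))[kind]
            v2 = comsia_fields(mol2, grid2, kinds=(kind,))[kind]
            assert np.max(np.abs(v1 - v2)) < 1e-9
        s1, e1 = comfa_fields(mol, grid)
        s2, e2 = comfa_fields(mol2, grid2)
        assert np.nanmax(np.abs(s1 - s2)) < 1e-9
        assert np.nanmax(np.abs(e1 - e2)) < 1e-9

    def test_deterministic_recomputation(self):
        mol = _atom_mol(hydrophobic_w=0.8, partial_charge=0.2)
        grid = make_grid([mol], 2.0, 4.0)
        v1 = comsia_fields(mol, grid, kinds=("steric",))["steric"]
        v2 = comsia_fields(mol, grid, kinds=("steric",))["steric"]
        assert np.array_equal(v1, v2)


class TestBlockAssembly:
    GRID = GridSpec((0.0, 0.0, 0.0), 1.0, (5, 1, 1))

    def test_constant_columns_dropped(self):
        x = np.array(
            [
                [1.0, 5.0, 3.0, 3.0, 0.0],
                [2.0, 5.0, 3.0, 3.0, 0.0],
                [4.0, 5.0, 3.0, 3.0, 0.0],
                [0.5, 5.0, 3.0, 3.0, 0.0],
            ]
        )  # columns 0 varies strongly, 1..4 constant
        x[:, 1] += np.array([0.0, 0.1, -0.1, 0.05])  # column 1 varies weakly
        block = build_block({"steric": x}, self.GRID, filter_sigma=0.5)
        assert block.kept_mask["steric"].sum() == 1
        block2 = build_block({"steric": x}, self.GRID, filter_sigma=0.01)
        assert block2.kept_mask["steric"].sum() == 2

    def test_equal_field_variance_after_scaling(self, rng):
        a = rng.normal(0, 5, (8, 5))
        b = rng.normal(0, 0.2, (8, 5))
        block = build_block({"steric": a, "hydrophobic": b}, self.GRID, filter_sigma=0.0)
        var = {
            k: block.matrix[:, block.columns_of(k)].var(axis=0, ddof=1).sum()
            for k in block.kinds
        }
        assert var["steric"] == pytest.approx(var["hydrophobic"], rel=1e-9)

    def test_nan_replaced_by_column_mean(self):
        x = np.array([[1.0, 0.0], [np.nan, 1.0], [3.0, 2.0], [4.0, 3.0]])
        x = np.hstack([x, np.zeros((4, 3))])
        block = build_block({"electrostatic": x}, self.GRID, filter_sigma=0.0, scaling="none")
        col0 = block.matrix[:, 0]
        assert col0[1] == pytest.approx((1 + 3 + 4) / 3)

    def test_all_filtered_is_error(self):
        x = np.ones((4, 5))
        with pytest.raises(ValueError, match="filtered"):
            build_block({"steric": x}, self.GRID, filter_sigma=1.0)

    def test_apply_block_matches_training_transform(self, rng):
        x = rng.normal(0, 3, (6, 5))
        block = build_block({"steric": x}, self.GRID, filter_sigma=0.1)
        again = apply_block({"steric": x}, block)
        assert np.allclose(again, block.matrix)
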