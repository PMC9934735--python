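"""Metric suite: bond inference, stability, validity, uniqueness, novelty,
energy ratio, and aggregate reports — against hand-built molecules."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gcdiff.metrics import (BondTable, atom_stability, batch_report,
                            energy_ratio, infer_bonds, molecule_stability,
                            novelty, uniqueness, validity)
from gcdiff.mol import Molecule


@pytest.fixture(scope="module")
def table():
    return BondTable.default()


def _water(stretch=None):
    ang = np.deg2rad(104.5)
    coords = np.array([[0, 0, 0], [0.96, 0, 0],
                       [0.96 * np.cos(ang), 0.96 * np.sin(ang), 0]])
    if stretch is not None:
        coords[1] = [stretch, 0.0, 0.0]
    return Molecule.from_symbols(["O", "H", "H"], coords)


def _methane():
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) \
        / np.sqrt(3) * 1.09
    return Molecule.from_symbols(["C", "H", "H", "H", "H"],
                                 np.vstack([[0, 0, 0], tet]))


class TestBondTable:
    def test_symmetric_lookup(self, table):
        assert table.length("O", "H", 1) == table.length("H", "O", 1) == 96

    def test_order_hierarchy_monotone(self, table):
        for pair in (("C", "C"), ("C", "N"), ("N", "N")):
            l1 = table.length(*pair, 1)
            l2 = table.length(*pair, 2)
            l3 = table.length(*pair, 3)
            if l2 is not None:
                assert l1 >= l2
            if l3 is not None:
                assert l2 >= l3

    @pytest.mark.parametrize("pair,dist,order", [
        (("O", "H"), 0.96, 1),
        (("H", "H"), 0.74, 1),
        (("C", "C"), 3.00, 0),
        (("C", "C"), 1.33, 2),
        (("C", "N"), 1.15, 3),
    ])
    def test_reference_assignments(self, table, pair, dist, order):
        assert table.bond_order(*pair, dist) == order

    def test_unknown_pair_is_nonbonded(self, table):
        assert table.bond_order("Hg", "F", 1.0) == 0

    def test_charge_aware_valencies(self, table):
        assert table.allowed_valences("N", 1) == (4,)
        assert table.allowed_valences("O", -1) == (1,)
        blind = BondTable.default(charge_aware=False)
        assert blind.allowed_valences("N", 1) == (3,)


class TestStability:
    def test_ideal_water_fully_stable(self, table):
        assert atom_stability(_water(), table) == 1.0
        assert molecule_stability(_water(), table)

    def test_lone_carbon_unstable(self, table):
        lone = Molecule.from_symbols(["C"], [[0, 0, 0]])
        assert atom_stability(lone, table) == 0.0

    def test_stretched_water_loses_stability(self, table):
        assert not molecule_stability(_water(stretch=2.5), table)

    def test_added_distant_atom_breaks_stability(self, table):
        m = _methane()
        worse = Molecule.from_symbols(m.symbols + ["C"],
                                      np.vstack([m.coords, [50.0, 0, 0]]))
        assert atom_stability(worse, table) < atom_stability(m, table)
        assert molecule_stability(m, table)
        assert not molecule_stability(worse, table)

    def test_stability_definition_link(self, table):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mol = Molecule.from_symbols(
                ["C", "H", "O"], rng.normal(size=(3, 3)) * 1.2)
            if molecule_stability(mol, table):
                assert atom_stability(mol, table) == 1.0


class TestBondInference:
    def test_invariance_under_rigid_motion_and_permutation(self, table):
        m = _methane()
        b0 = infer_bonds(m, table)
        R = Rotation.random(random_state=1).as_matrix()
        moved = Molecule.from_symbols(m.symbols, m.coords @ R.T + 3.0)
        assert np.array_equal(infer_bonds(moved, table), b0)
        perm = np.array([2, 0, 4, 1, 3])
        permuted = Molecule.from_symbols([m.symbols[i] for i in perm],
                                         m.coords[perm])
        assert np.array_equal(infer_bonds(permuted, table),
                              b0[np.ix_(perm, perm)])

    def test_symmetric_zero_diagonal(self, table):
        b = infer_bonds(_water(), table)
        assert np.array_equal(b, b.T)
        assert np.all(np.diag(b) == 0)


class TestValidity:
    def test_water_canonicalizes_to_O(self, table):
        ok, smiles = validity(_water(), table)
        assert ok and smiles == "O"

    def test_pentavalent_carbon_invalid(self, table):
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1]]) * 1.09
        pent = Molecule.from_symbols(["C"] + ["H"] * 5,
                                     np.vstack([[0, 0, 0], dirs]))
        ok, smiles = validity(pent, table)
        assert not ok and smiles is None


class TestSetMetrics:
    def test_uniqueness_counting(self):
        assert uniqueness(["O", "O", "C"]) == pytest.approx(2 / 3)
        assert uniqueness(["A", "B", "C"]) == 1.0
        assert uniqueness(["A"] * 5) == pytest.approx(1 / 5)
        with pytest.raises(ValueError):
            uniqueness([])

    def test_novelty_extremes_and_half(self):
        assert novelty(["O", "C"], {"O", "C", "N"}) == 0.0
        assert novelty(["O", "C"], {"N"}) == 1.0
        assert novelty(["A", "B", "C", "D"], {"A", "B"}) == 0.5


class TestBatchReport:
    def test_hand_counted_aggregate(self, table):
        rep = batch_report([_water(),
                            Molecule.from_symbols(["C"], [[0, 0, 0]])], table)
        assert rep["atom_stability_pct"] == pytest.approx(75.0)
        assert rep["molecule_stability_pct"] == pytest.approx(50.0)

    def test_valid_and_unique_bounded_by_validity(self, table):
        rng = np.random.default_rng(2)
        mols = [Molecule.from_symbols(["O", "H", "H"],
                                      rng.normal(size=(3, 3)))
                for _ in range(10)] + [_water()] * 5
        rep = batch_report(mols, table)
        assert rep["valid_and_unique_pct"] <= rep["validity_pct"] <= 100.0

    def test_empty_rejected(self, table):
        with pytest.raises(ValueError):
            batch_report([], table)


class TestEnergyRatio:
    def test_near_equilibrium_conformation_not_flagged(self, table):
        ratio, flagged = energy_ratio(_methane(), table, n_conformers=10,
                                      rng=np.random.default_rng(0))
        assert ratio is not None
        assert ratio < 7.0 and flagged is False

    def test_unsanitizable_input_reports_reason(self, table):
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1]]) * 1.09
        pent = Molecule.from_symbols(["C"] + ["H"] * 5,
                                     np.vstack([[0, 0, 0], dirs]))
        ratio, reason = energy_ratio(pent, table, n_conformers=5)
        assert ratio is None and isinstance(reason, str)
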