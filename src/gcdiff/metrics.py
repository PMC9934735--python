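"""Molecule-quality metrics: distance-based bond inference, atom and
molecule stability, RDKit validity, uniqueness, novelty, and the
conformer energy ratio.

Bonds are never read from files: they are inferred from atom types and
inter-atomic distances against a reference bond-length table, matching
the implicit-bond scoring convention of the diffusion-generation
literature.  Atom stability (AS) is the fraction of atoms whose summed
inferred bond orders hit an allowed valence for the element (and formal
charge, when the table is charge-aware); a molecule is stable (MS) iff
every atom is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from . import bond_data
from .mol import Molecule

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}


@dataclass
class BondTable:
    """Per-element-pair reference bond lengths (pm), margins, valencies."""

    ref_lengths: Dict[Tuple[str, str, int], float]
    margins: Dict[int, float]
    valencies: Dict[str, Dict[int, Tuple[int, ...]]]
    charge_aware: bool = True
    _warned: Set[Tuple[str, str]] = field(default_factory=set, repr=False)

    def length(self, a: str, b: str, order: int) -> Optional[float]:
        return (self.ref_lengths.get((a, b, order))
                or self.ref_lengths.get((b, a, order)))

    def bond_order(self, a: str, b: str, dist_angstrom: float) -> int:
        """Highest order whose length + margin envelope contains the distance."""
        d = dist_angstrom * 100.0  # Å → pm
        if all(self.length(a, b, o) is None for o in (1, 2, 3)):
            if (a, b) not in self._warned and (b, a) not in self._warned:
                self._warned.add((a, b))
                logger.info("no reference lengths for pair (%s, %s); "
                            "treating as non-bonded", a, b)
            return 0
        best = 0
        for order in (1, 2, 3):
            ref = self.length(a, b, order)
            if ref is not None and d < ref + self.margins[order]:
                best = order
        return best

    def allowed_valences(self, element: str, charge: int = 0) -> Tuple[int, ...]:
        table = self.valencies.get(element)
        if table is None:
            return ()
        if self.charge_aware and charge in table:
            return table[charge]
        return table.get(0, ())

    @classmethod
    def default(cls, charge_aware: bool = True) -> "BondTable":
        ref = {}
        for (a, b), v in bond_data.BONDS1.items():
            ref[(a, b, 1)] = float(v)
        for (a, b), v in bond_data.BONDS2.items():
            ref[(a, b, 2)] = float(v)
        for (a, b), v in bond_data.BONDS3.items():
            ref[(a, b, 3)] = float(v)
        return cls(ref_lengths=ref, margins=dict(bond_data.MARGINS),
                   valencies=bond_data.VALENCIES, charge_aware=charge_aware)


@dataclass
class MoleculeReport:
    atom_stable_frac: float
    mol_stable: bool
    valid: bool
    canonical_string: Optional[str] = None


def infer_bonds(mol: Molecule, table: BondTable) -> np.ndarray:
    """Symmetric N×N integer bond-order matrix from pair distances."""
    n = mol.n_atoms
    symbols = mol.symbols
    diff = mol.coords[:, None, :] - mol.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    orders = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            o = table.bond_order(symbols[i], symbols[j], dist[i, j])
            orders[i, j] = orders[j, i] = o
    return orders


def atom_stability(mol: Molecule, table: BondTable,
                   bonds: Optional[np.ndarray] = None) -> float:
    """Fraction of atoms whose summed bond orders match an allowed valence."""
    if bonds is None:
        bonds = infer_bonds(mol, table)
    total = bonds.sum(axis=1)
    ok = 0
    for sym, q, v in zip(mol.symbols, mol.charges, total):
        if int(v) in table.allowed_valences(sym, int(q)):
            ok += 1
    return ok / mol.n_atoms


def molecule_stability(mol: Molecule, table: BondTable,
                       bonds: Optional[np.ndarray] = None) -> bool:
    """True iff every atom has exactly an allowed valence."""
    return atom_stability(mol, table, bonds=bonds) == 1.0


def _to_rdkit(mol: Molecule, bonds: np.ndarray) -> Chem.Mol:
    rw = Chem.RWMol()
    for sym, q in zip(mol.symbols, mol.charges):
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(int(q))
        rw.AddAtom(atom)
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if bonds[i, j] > 0:
                rw.AddBond(i, j, _BOND_TYPES[int(bonds[i, j])])
    conf = Chem.Conformer(n)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m = rw.GetMol()
    m.AddConformer(conf)
    return m


def validity(mol: Molecule, table: BondTable,
             bonds: Optional[np.ndarray] = None):
    """RDKit sanitization of the inferred bond graph.

    Returns ``(valid, canonical_smiles)``; the SMILES is of the largest
    fragment, so disconnected graphs are scored by their main component.
    """
    if bonds is None:
        bonds = infer_bonds(mol, table)
    rdmol = _to_rdkit(mol, bonds)
    try:
        Chem.SanitizeMol(rdmol)
        smiles = Chem.MolToSmiles(rdmol)
        if smiles is None or smiles == "":
            return False, None
        # largest-fragment convention
        frags = smiles.split(".")
        largest = max(frags, key=len)
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(largest))
        if canon is None:
            return False, None
        return True, canon
    except (Chem.rdchem.AtomValenceException,
            Chem.rdchem.KekulizeException,
            Chem.rdchem.AtomKekulizeException,
            ValueError, RuntimeError):
        return False, None


def uniqueness(strings: Sequence[str]) -> float:
    """|distinct| / |list| over canonical SMILES."""
    if len(strings) == 0:
        raise ValueError("uniqueness of an empty list is undefined")
    return len(set(strings)) / len(strings)


def novelty(strings: Sequence[str], reference: Set[str]) -> float:
    """Fraction of (valid, unique) strings absent from the reference set."""
    distinct = set(strings)
    if not distinct:
        return 0.0
    return sum(1 for s in distinct if s not in reference) / len(distinct)


def energy_ratio(mol: Molecule, table: Optional[BondTable] = None,
                 n_conformers: int = 50,
                 rng: Optional[np.random.Generator] = None,
                 threshold: float = 7.0):
    """UFF energy of the input conformation over the mean UFF energy of
    ETKDGv3-embedded conformers of the same molecular graph.

    Returns ``(ratio, flagged)`` where ``flagged`` marks ratios above the
    highly-unlikely-conformation threshold (7), or ``(None, reason)`` when
    embedding or the force field fails.
    """
    table = table or BondTable.default()
    bonds = infer_bonds(mol, table)
    rdmol = _to_rdkit(mol, bonds)
    try:
        Chem.SanitizeMol(rdmol)
    except Exception:
        return None, "sanitization failed"
    try:
        ff = AllChem.UFFGetMoleculeForceField(rdmol)
        if ff is None:
            return None, "no UFF parameters"
        e_input = ff.CalcEnergy()
        probe = Chem.Mol(rdmol)
        probe.RemoveAllConformers()
        params = AllChem.ETKDGv3()
        params.randomSeed = int(rng.integers(0, 2**31 - 1)) if rng else 0xF00D
        ids = AllChem.EmbedMultipleConfs(probe, numConfs=n_conformers,
                                         params=params)
        if len(ids) == 0:
            return None, "conformer embedding failed"
        energies = []
        for cid in ids:
            ffc = AllChem.UFFGetMoleculeForceField(probe, confId=cid)
            energies.append(ffc.CalcEnergy())
        mean_e = float(np.mean(energies))
        if mean_e == 0.0:
            return None, "zero reference energy"
        ratio = e_input / mean_e
        return float(ratio), bool(ratio > threshold)
    except Exception as exc:   # force-field edge cases
        return None, f"energy evaluation failed: {exc}"


def batch_report(mols: Sequence[Molecule], table: BondTable,
                 reference: Optional[Set[str]] = None) -> Dict:
    """Aggregate AS/MS/Val/Val∧Uniq (and Novel) percentages with counts."""
    if len(mols) == 0:
        raise ValueError("empty molecule list")
    n = len(mols)
    as_fracs, ms_flags, valid_flags, smiles = [], [], [], []
    for mol in mols:
        bonds = infer_bonds(mol, table)
        af = atom_stability(mol, table, bonds=bonds)
        as_fracs.append(af * mol.n_atoms)
        ms_flags.append(af == 1.0)
        ok, canon = validity(mol, table, bonds=bonds)
        valid_flags.append(ok)
        if ok:
            smiles.append(canon)
    n_atoms = sum(m.n_atoms for m in mols)
    report = {
        "n_molecules": n,
        "n_atoms": n_atoms,
        "atom_stability_pct": 100.0 * sum(as_fracs) / n_atoms,
        "molecule_stability_pct": 100.0 * sum(ms_flags) / n,
        "validity_pct": 100.0 * sum(valid_flags) / n,
        "valid_and_unique_pct": 100.0 * len(set(smiles)) / n,
    }
    if reference is not None:
        vu = set(smiles)
        report["novelty_pct"] = 100.0 * novelty(sorted(vu), reference) \
            if vu else 0.0
    return report
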