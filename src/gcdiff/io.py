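"""Reading and writing molecules: XYZ, SDF (MOL V2000), and a compact
NPZ dataset container for larger processed sets.

Bond blocks in SDF files are ignored on read: bonds are always inferred
downstream from atom types and inter-atomic distances (the implicit-bond
paradigm used by the metrics module).
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .mol import Molecule, QM9_VOCAB, VocabularyError


class ParseError(ValueError):
    """A record in a molecule file does not follow the named standard."""


def read_molecules(path: str, format: Optional[str] = None,
                   vocab: Sequence[str] = QM9_VOCAB,
                   permissive: bool = False) -> List[Molecule]:
    """Read molecules from an XYZ or SDF file.

    Elements outside ``vocab`` raise :class:`VocabularyError`, or skip the
    offending molecule when ``permissive`` is set.
    """
    fmt = format or os.path.splitext(path)[1].lstrip(".").lower()
    if fmt == "xyz":
        records = _read_xyz(path)
    elif fmt in ("sdf", "mol"):
        records = _read_sdf(path)
    else:
        raise ValueError(f"unknown molecule format {fmt!r}")
    mols = []
    for symbols, coords, charges in records:
        try:
            mols.append(Molecule.from_symbols(symbols, coords, charges,
                                              vocab=vocab))
        except VocabularyError:
            if not permissive:
                raise
    return mols


def write_molecules(mols: Sequence[Molecule], path: str,
                    format: Optional[str] = None) -> None:
    """Write molecules to XYZ or SDF; round-trips coordinates to 1e-4 Å."""
    fmt = format or os.path.splitext(path)[1].lstrip(".").lower()
    if fmt == "xyz":
        _write_xyz(mols, path)
    elif fmt in ("sdf", "mol"):
        _write_sdf(mols, path)
    else:
        raise ValueError(f"unknown molecule format {fmt!r}")


# -- XYZ ----------------------------------------------------------------------

def _read_xyz(path: str):
    records = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0:
            raise ParseError(f"{path}:{i + 1}: truncated XYZ block")
        symbols, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: malformed atom line")
            symbols.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        records.append((symbols, np.array(coords), None))
        i += 2 + n
    return records


def _write_xyz(mols, path):
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{mol.n_atoms}\n")
            props = ""
            if mol.property_labels:
                props = " ".join(f"{k}={v:.6f}"
                                 for k, v in sorted(mol.property_labels.items()))
            fh.write(props + "\n")
            for sym, (x, y, z) in zip(mol.symbols, mol.coords):
                fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")


# -- SDF ----------------------------------------------------------------------

def _read_sdf(path: str):
    supplier = Chem.SDMolSupplier(path, sanitize=False, removeHs=False)
    records = []
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"{path}: record {idx + 1} failed to parse")
        conf = rdmol.GetConformer()
        symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
        charges = np.array([a.GetFormalCharge() for a in rdmol.GetAtoms()],
                           dtype=np.int64)
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(rdmol.GetNumAtoms())])
        records.append((symbols, coords, charges))
    return records


def _write_sdf(mols, path):
    writer = Chem.SDWriter(path)
    try:
        for mol in mols:
            rw = Chem.RWMol()
            for sym, q in zip(mol.symbols, mol.charges):
                atom = Chem.Atom(sym)
                atom.SetFormalCharge(int(q))
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
            conf = Chem.Conformer(mol.n_atoms)
            for i, (x, y, z) in enumerate(mol.coords):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            m = rw.GetMol()
            m.AddConformer(conf)
            writer.write(m)
    finally:
        writer.close()


# -- compact dataset container ------------------------------------------------

def save_dataset(mols: Sequence[Molecule], path: str) -> None:
    """Save a molecule list as flat NPZ arrays (coords, types, charges, sizes)."""
    sizes = np.array([m.n_atoms for m in mols], dtype=np.int64)
    coords = np.concatenate([m.coords for m in mols], axis=0)
    types = np.concatenate([np.argmax(m.atom_types, axis=1) for m in mols])
    charges = np.concatenate([m.charges for m in mols])
    vocab = np.array(list(mols[0].vocab))
    np.savez_compressed(path, sizes=sizes, coords=coords, types=types,
                        charges=charges, vocab=vocab)


def load_dataset(path: str) -> List[Molecule]:
    data = np.load(path, allow_pickle=False)
    vocab = tuple(str(s) for s in data["vocab"])
    offsets = np.concatenate([[0], np.cumsum(data["sizes"])])
    mols = []
    for i, n in enumerate(data["sizes"]):
        sl = slice(offsets[i], offsets[i + 1])
        onehot = np.zeros((n, len(vocab)))
        onehot[np.arange(n), data["types"][sl]] = 1.0
        mols.append(Molecule(data["coords"][sl], onehot,
                             data["charges"][sl], vocab))
    return mols
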