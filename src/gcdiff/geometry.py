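"""Rigid alignment utilities: Kabsch superposition with per-element
atom matching (proper rotations only, so enantiomers stay distinct)."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .mol import Molecule, remove_com


def kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimizing ‖P R − Q‖ (inputs centered)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def aligned_rmsd(mol_a: Molecule, mol_b: Molecule,
                 n_restarts: int = 8, n_iters: int = 30,
                 rng: Optional[np.random.Generator] = None) -> float:
    """Best RMSD over proper rotations and same-element atom permutations.

    Alternates Hungarian matching within each element class with Kabsch
    re-alignment, restarted from several random rotations; exact for the
    small rigid templates this package ships.
    """
    if mol_a.n_atoms != mol_b.n_atoms:
        raise ValueError("molecules must have the same number of atoms")
    if sorted(mol_a.symbols) != sorted(mol_b.symbols):
        raise ValueError("molecules must share an element composition")
    rng = rng or np.random.default_rng(0)
    P0 = remove_com(mol_a.coords)
    Q = remove_com(mol_b.coords)
    sym_a = np.array(mol_a.symbols)
    sym_b = np.array(mol_b.symbols)
    groups = [(np.where(sym_a == s)[0], np.where(sym_b == s)[0])
              for s in sorted(set(sym_a))]

    best = np.inf
    for r in range(n_restarts):
        R = np.eye(3) if r == 0 else Rotation.random(
            random_state=int(rng.integers(0, 2**31 - 1))).as_matrix()
        P = P0 @ R.T
        perm = np.arange(len(P))
        prev = np.inf
        for _ in range(n_iters):
            # match atoms within element classes
            for ia, ib in groups:
                cost = ((P[ia][:, None, :] - Q[ib][None, :, :]) ** 2).sum(axis=2)
                ri, ci = linear_sum_assignment(cost)
                perm[ia[ri]] = ib[ci]
            Qp = Q[perm]
            Rk = kabsch(P, Qp)
            P = P @ Rk
            rmsd = float(np.sqrt(((P - Qp) ** 2).sum() / len(P)))
            if abs(prev - rmsd) < 1e-12:
                break
            prev = rmsd
        best = min(best, prev)
    return best


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=int(rng.integers(0, 2**31 - 1))).as_matrix()
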