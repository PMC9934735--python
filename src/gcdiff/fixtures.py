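"""Synthetic molecular fixtures: rigid templates with Gaussian jitter,
random rotations, toy scalar properties, and a matching toy bond table.

Four templates cover the behaviors the diffusion stack must learn:
a tetrahedral methane-like molecule, a bent water-like molecule, a linear
hydrogen-cyanide-like molecule (with a triple bond), and a chiral
five-atom scaffold (a central carbon with four distinct substituents)
whose mirror image is not superimposable.  Ideal bonded distances sit
inside the toy bond-table envelopes and all non-bonded distances outside,
so an unjittered dataset scores AS = MS = 100% by construction.

The toy table restricts the real reference lengths to template pairs but
widens the margins (25 pm single, 12 pm triple): with the default 0.05 Å
per-coordinate jitter, bond lengths fluctuate with ≈7 pm standard
deviation, which the real 10/5/3 pm scoring margins would misclassify
far too often for a fixture meant to be near-perfectly stable.  The toy
valency map accepts the valences realized in the templates (N: 1 or 3,
O: 1 or 2).  Test-only: real data is always scored with the real table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .geometry import random_rotation
from .metrics import BondTable
from .mol import Molecule, remove_com

TOY_JITTER_SD = 0.05      # Å, default dataset jitter
TOY_DATASET_SIZE = 2000

# fixed pseudo-charges for the dipole-like property (arbitrary but frozen)
_PSEUDO_CHARGES = {"H": 0.4, "C": 0.0, "N": -0.3, "O": -0.4, "F": -0.5}

_TET = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                 [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]) / np.sqrt(3.0)


@dataclass
class Template:
    name: str
    coords: np.ndarray          # (N, 3) ideal geometry, CoM-centered, Å
    types: Sequence[str]
    property_fn: str = "radius_of_gyration"

    def molecule(self) -> Molecule:
        return Molecule.from_symbols(self.types, self.coords)


def make_templates() -> List[Template]:
    """The four rigid templates, CoM-centered."""
    templates = []

    # tetrahedral CH4-like, C–H 1.09 Å
    coords = np.vstack([[0.0, 0.0, 0.0], 1.09 * _TET])
    templates.append(Template("methane", remove_com(coords),
                              ["C", "H", "H", "H", "H"]))

    # bent H2O-like, O–H 0.96 Å, 104.5°
    ang = np.deg2rad(104.5)
    coords = np.array([[0.0, 0.0, 0.0],
                       [0.96, 0.0, 0.0],
                       [0.96 * np.cos(ang), 0.96 * np.sin(ang), 0.0]])
    templates.append(Template("water", remove_com(coords), ["O", "H", "H"]))

    # linear HCN-like, H–C 1.065 Å, C≡N 1.155 Å
    coords = np.array([[-1.065, 0.0, 0.0], [0.0, 0.0, 0.0],
                       [1.155, 0.0, 0.0]])
    templates.append(Template("hydrogen_cyanide", remove_com(coords),
                              ["H", "C", "N"]))

    # chiral scaffold: central C, four distinct substituents at tetrahedral
    # directions with their standard single-bond lengths
    lengths = {"H": 1.09, "N": 1.47, "O": 1.43, "F": 1.35}
    subs = ["H", "N", "O", "F"]
    coords = np.vstack([[0.0, 0.0, 0.0]]
                       + [lengths[s] * _TET[k] for k, s in enumerate(subs)])
    templates.append(Template("chiral", remove_com(coords), ["C"] + subs))
    return templates


def toy_bond_table() -> BondTable:
    """Bond table restricted to template pairs with jitter-robust margins."""
    real = BondTable.default()
    pairs1 = [("H", "C"), ("H", "O"), ("C", "N"), ("C", "O"), ("C", "F")]
    ref = {(a, b, 1): real.length(a, b, 1) for a, b in pairs1}
    ref[("C", "N", 3)] = real.length("C", "N", 3)
    valencies = {
        "H": {0: (1,)},
        "C": {0: (4,)},
        "N": {0: (1, 3)},
        "O": {0: (1, 2)},
        "F": {0: (1,)},
    }
    return BondTable(ref_lengths=ref,
                     margins={1: 25.0, 2: 12.0, 3: 12.0},
                     valencies=valencies)


def toy_property(mol: Molecule, name: str = "radius_of_gyration") -> float:
    """Deterministic rotation-invariant scalar properties.

    ``radius_of_gyration`` = sqrt(mean ‖x_i − x̄‖²) stands in for size-like
    properties (polarizability); ``dipole_like`` = ‖Σ q_i x_i‖ with fixed
    per-element pseudo-charges stands in for the dipole moment.
    """
    x = remove_com(mol.coords)
    if name == "radius_of_gyration":
        return float(np.sqrt((x**2).sum(axis=1).mean()))
    if name == "dipole_like":
        q = np.array([_PSEUDO_CHARGES[s] for s in mol.symbols])
        return float(np.linalg.norm((q[:, None] * x).sum(axis=0)))
    raise ValueError(f"unknown toy property {name!r}")


def sample_dataset(templates: Optional[Sequence[Template]] = None,
                   n: int = TOY_DATASET_SIZE,
                   jitter_sd: float = TOY_JITTER_SD,
                   rng: Optional[np.random.Generator] = None,
                   property_names: Sequence[str] = ("radius_of_gyration",
                                                    "dipole_like"),
                   ) -> List[Molecule]:
    """Draw n molecules: random template, Gaussian jitter, random rotation.

    Property labels are evaluated on the jittered geometry, so conditional
    models see a continuum of values rather than four constants.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    templates = list(templates) if templates is not None else make_templates()
    rng = rng or np.random.default_rng(0)
    mols = []
    for _ in range(n):
        tpl = templates[rng.integers(0, len(templates))]
        coords = tpl.coords + rng.normal(0.0, jitter_sd, size=tpl.coords.shape)
        coords = remove_com(coords) @ random_rotation(rng).T
        mol = Molecule.from_symbols(tpl.types, remove_com(coords))
        mol.property_labels = {name: toy_property(mol, name)
                               for name in property_names}
        mol.property_labels["template"] = float(templates.index(tpl))
        mols.append(mol)
    return mols
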