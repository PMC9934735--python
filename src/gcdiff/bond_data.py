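"""Reference bond lengths (pm), order margins, and allowed valencies.

The lookup convention: a pair of atoms at distance d (pm) is assigned the
highest bond order whose reference length plus margin still exceeds d.
Margins default to 10/5/3 pm for orders 1/2/3.  Lengths are standard
experimental equilibrium bond lengths for the light-element pairs the
QM9 vocabulary uses, plus common halogen/heteroatom pairs for larger
vocabularies; pairs absent from the table are treated as non-bonded.
"""

# single bonds, pm
BONDS1 = {
    ("H", "H"): 74, ("H", "C"): 109, ("H", "N"): 101, ("H", "O"): 96,
    ("H", "F"): 92, ("H", "S"): 134, ("H", "Cl"): 127, ("H", "Br"): 141,
    ("H", "I"): 161, ("H", "P"): 144, ("H", "Si"): 148, ("H", "B"): 119,
    ("C", "C"): 154, ("C", "N"): 147, ("C", "O"): 143, ("C", "F"): 135,
    ("C", "S"): 182, ("C", "Cl"): 177, ("C", "Br"): 194, ("C", "I"): 214,
    ("C", "P"): 184, ("C", "Si"): 185, ("C", "B"): 156,
    ("N", "N"): 145, ("N", "O"): 140, ("N", "F"): 136, ("N", "S"): 168,
    ("N", "Cl"): 175, ("N", "P"): 177,
    ("O", "O"): 148, ("O", "F"): 142, ("O", "S"): 151, ("O", "P"): 163,
    ("O", "Si"): 163, ("O", "B"): 136, ("O", "Cl"): 170,
    ("F", "F"): 142, ("S", "S"): 204, ("P", "P"): 221, ("Si", "Si"): 233,
    ("Cl", "Cl"): 199, ("Br", "Br"): 228, ("I", "I"): 266,
}

# double bonds, pm
BONDS2 = {
    ("C", "C"): 134, ("C", "N"): 129, ("C", "O"): 120, ("C", "S"): 160,
    ("N", "N"): 125, ("N", "O"): 121, ("O", "O"): 121, ("P", "O"): 150,
    ("S", "O"): 143, ("P", "P"): 201,
}

# triple bonds, pm
BONDS3 = {
    ("C", "C"): 120, ("C", "N"): 116, ("C", "O"): 113, ("N", "N"): 110,
}

MARGINS = {1: 10.0, 2: 5.0, 3: 3.0}

# allowed valence per element; charge-aware variants where chemistry differs
VALENCIES = {
    "H": {0: (1,)},
    "B": {0: (3,)},
    "C": {0: (4,), 1: (3,), -1: (3,)},
    "N": {0: (3,), 1: (4,), -1: (2,)},
    "O": {0: (2,), 1: (3,), -1: (1,)},
    "F": {0: (1,), -1: (0,)},
    "Al": {0: (3,)},
    "Si": {0: (4,)},
    "P": {0: (3, 5), 1: (4,)},
    "S": {0: (2, 4, 6), 1: (3,), -1: (1,)},
    "Cl": {0: (1,)},
    "As": {0: (3, 5)},
    "Br": {0: (1,)},
    "I": {0: (1,)},
    "Hg": {0: (1, 2)},
    "Bi": {0: (3, 5)},
}
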