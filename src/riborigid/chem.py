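"""Chemical reference tables for standard ribonucleotides.

Covalent-bond templates, hydrogen-bond donor/acceptor lists, van der Waals
radii and atomic masses used when turning a structure into a body-bar
constraint network. Only the four standard bases A/C/G/U are supported.
"""

from __future__ import annotations

# -- atomic masses (amu) ------------------------------------------------------

ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "MG": 24.305,
}

# van der Waals radii (Angstrom), used by the hydrophobic-tether criterion
VDW_RADIUS = {"C": 1.70, "S": 1.80, "N": 1.55, "O": 1.52, "P": 1.80, "H": 1.20}

# -- residue name normalisation -----------------------------------------------

RNA_RESNAMES = {
    "A": "A", "RA": "A", "ADE": "A", "A3": "A", "A5": "A", "AN": "A",
    "C": "C", "RC": "C", "CYT": "C", "C3": "C", "C5": "C", "CN": "C",
    "G": "G", "RG": "G", "GUA": "G", "G3": "G", "G5": "G", "GN": "G",
    "U": "U", "RU": "U", "URA": "U", "U3": "U", "U5": "U", "UN": "U",
}
WATER_RESNAMES = {"HOH", "WAT", "H2O", "TIP3", "SPC"}
MG_RESNAMES = {"MG", "MG2"}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

#: glycosidic nitrogen of the base, also the atom the per-nucleotide
#: largest-rigid-cluster bookkeeping is projected from for pyrimidines.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

# -- covalent bond templates --------------------------------------------------
# Backbone + ribose bonds shared by all four nucleotides (heavy atoms and
# hydrogens; primes written with ' as in PDB v3 names).

_BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"),
    ("O5'", "C5'"), ("C5'", "C4'"), ("C4'", "C3'"), ("C3'", "O3'"),
    ("C4'", "O4'"), ("O4'", "C1'"), ("C1'", "C2'"), ("C2'", "C3'"),
    ("C2'", "O2'"),
    # hydrogens
    ("C5'", "H5'"), ("C5'", "H5''"), ("C4'", "H4'"), ("C3'", "H3'"),
    ("C2'", "H2'"), ("C1'", "H1'"), ("O2'", "HO2'"),
    # chain termini
    ("O5'", "HO5'"), ("O3'", "HO3'"), ("P", "OP3"),
]

_BASE_BONDS = {
    "A": [
        ("C1'", "N9"),
        ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"),
        ("C6", "N6"), ("C6", "N1"), ("N1", "C2"), ("C2", "N3"),
        ("N3", "C4"), ("C4", "C5"), ("C4", "N9"),
        ("C8", "H8"), ("C2", "H2"), ("N6", "H61"), ("N6", "H62"),
    ],
    "G": [
        ("C1'", "N9"),
        ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"),
        ("C6", "O6"), ("C6", "N1"), ("N1", "C2"), ("C2", "N2"),
        ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C4", "N9"),
        ("C8", "H8"), ("N1", "H1"), ("N2", "H21"), ("N2", "H22"),
    ],
    "C": [
        ("C1'", "N1"),
        ("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"),
        ("C4", "N4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1"),
        ("C5", "H5"), ("C6", "H6"), ("N4", "H41"), ("N4", "H42"),
    ],
    "U": [
        ("C1'", "N1"),
        ("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"),
        ("C4", "O4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1"),
        ("C5", "H5"), ("C6", "H6"), ("N3", "H3"),
    ],
}


def template_bonds(base: str) -> list[tuple[str, str]]:
    """All template bonds (backbone + base) for one nucleotide of ``base``."""
    return _BACKBONE_BONDS + _BASE_BONDS[base]


#: atoms that belong to the base moiety (everything that is replaced when a
#: base is transplanted); the glycosidic bond itself stays with the sugar.
BASE_ATOMS = {
    b: sorted({a for bond in _BASE_BONDS[b] for a in bond} - {"C1'"})
    for b in _BASE_BONDS
}

_SUGAR_BACKBONE_ATOMS = sorted(
    {a for bond in _BACKBONE_BONDS for a in bond}
)


def is_base_atom(base: str, name: str) -> bool:
    return name in BASE_ATOMS.get(base, ())


# -- bond-order bookkeeping ----------------------------------------------------
# Bonds with hindered rotation are modelled with 6 bars (locked), freely
# rotatable single bonds with 5.  All bonds inside the conjugated nucleobase
# (ring plus exocyclic carbonyl/amino groups) are locked; the glycosidic bond
# and all sugar/backbone single bonds rotate.

_LOCKED = {}
for _b, _bonds in _BASE_BONDS.items():
    for _i, _j in _bonds:
        if _i == "C1'" or _j == "C1'":
            continue  # glycosidic: rotatable (chi dihedral)
        _LOCKED.setdefault(_b, set()).add(frozenset((_i, _j)))


def is_locked_bond(base: str, name_i: str, name_j: str) -> bool:
    """True for bonds with hindered rotation (6 bars in the network)."""
    return frozenset((name_i, name_j)) in _LOCKED.get(base, set())


# -- hydrogen-bond donors and acceptors ---------------------------------------
# donor heavy atom -> names of its polar hydrogens
DONORS = {
    "A": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42")},
    "U": {"N3": ("H3",)},
}
_SUGAR_DONORS = {"O2'": ("HO2'",), "O3'": ("HO3'",), "O5'": ("HO5'",)}

ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N7", "N3"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}
_SUGAR_ACCEPTORS = ("O2'", "O3'", "O4'", "O5'", "OP1", "OP2", "OP3")

#: acceptors treated as sp2 (carbonyl / aromatic N); everything else sp3
SP2_ATOMS = {
    "O6", "O2", "O4", "N1", "N3", "N7", "OP1", "OP2", "OP3",
    "N2", "N4", "N6",
}


def donors_of(base: str) -> dict[str, tuple[str, ...]]:
    d = dict(_SUGAR_DONORS)
    d.update(DONORS.get(base, {}))
    return d


def acceptors_of(base: str) -> tuple[str, ...]:
    return tuple(ACCEPTORS.get(base, ())) + _SUGAR_ACCEPTORS
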