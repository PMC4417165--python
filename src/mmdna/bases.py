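"""Reduced-atom nucleobase chemistry.

Each nucleotide carries the heavy ring atoms of its base, the exocyclic
hydrogen-bond partners, C1', a pseudo-O4' (placed by the builder to realise a
requested glycosidic torsion) and one pseudo-P at a fixed fiber-B offset in
the base frame.  This is enough chemistry for frame fitting, hydrogen-bond
and pairing analysis, chi conformers and groove geometry; no full backbone is
modelled.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

__all__ = [
    "STANDARD_BASES",
    "RING_ATOMS",
    "PURINES",
    "PYRIMIDINES",
    "COMPLEMENT",
    "GLYCOSIDIC_N",
    "CHI_REF_ATOM",
    "CHI_ATOMS",
    "DONORS",
    "ACCEPTORS",
    "P_OFFSET",
    "base_atom_names",
    "standard_coords",
    "ring_coords",
]


def _load_standard_bases() -> dict[str, dict[str, np.ndarray]]:
    text = resources.files("mmdna").joinpath("data/standard_bases.json").read_text()
    raw = json.loads(text)
    return {
        base: {name: np.asarray(xyz, dtype=float) for name, xyz in atoms.items()}
        for base, atoms in raw["bases"].items()
    }


#: idealized base-atom coordinates in the standard reference frame (A)
STANDARD_BASES: dict[str, dict[str, np.ndarray]] = _load_standard_bases()

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T"})
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: heavy ring atoms used for least-squares frame fitting
RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}
#: fourth chi atom: chi = O4'-C1'-N9-C4 (purines), O4'-C1'-N1-C2 (pyrimidines)
CHI_REF_ATOM = {"A": "C4", "G": "C4", "C": "C2", "T": "C2"}
CHI_ATOMS = {b: ("O4'", "C1'", GLYCOSIDIC_N[b], CHI_REF_ATOM[b]) for b in "ACGT"}

# Hydrogen-bond donors: atom -> ("amine", attached ring atom) for exocyclic
# NH2 groups, or ("ring", (neighbour, neighbour)) for ring N-H donors.  The
# geometry module constructs idealized in-plane hydrogens from these.
DONORS: dict[str, dict[str, tuple]] = {
    "A": {"N6": ("amine", "C6")},
    "G": {"N1": ("ring", ("C2", "C6")), "N2": ("amine", "C2")},
    "C": {"N4": ("amine", "C4")},
    "T": {"N3": ("ring", ("C2", "C4"))},
}

# Hydrogen-bond acceptors (base heavy atoms; O4' of the sugar is accepted on
# every residue in addition to these).
ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "T": ("O2", "O4"),
}

SUGAR_ACCEPTOR = "O4'"

#: pseudo-phosphate offset in the base frame, calibrated so a straight
#: fiber-like build reproduces canonical B-DNA cross-strand P-P separations
#: (minor groove ~11.7 A, major ~17.2 A, P radius ~9.2 A)
P_OFFSET = np.array([-2.75, 8.80, 0.0])

# pseudo-O4' internal coordinates off C1' (bond A, angle deg vs glycosidic N)
O4P_BOND = 1.42
O4P_ANGLE = 108.2


def base_atom_names(base: str) -> list[str]:
    """All atom names carried by a built nucleotide of this base type."""
    return list(STANDARD_BASES[base].keys()) + ["O4'", "P"]


def standard_coords(base: str, names=None) -> np.ndarray:
    atoms = STANDARD_BASES[base]
    if names is None:
        names = list(atoms.keys())
    return np.array([atoms[n] for n in names])


def ring_coords(base: str) -> np.ndarray:
    return standard_coords(base, RING_ATOMS[base])
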