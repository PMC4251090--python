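"""Amino-acid chemistry tables: chi definitions, ideal side-chain geometry,
Lennard-Jones atom parameters and symmetry sets.

Side-chain templates are Z-matrix rows derived from ideal (energy-minimised)
amino-acid component geometry: each row places one heavy atom from three
previously known atoms via (bond length [angstrom], bond angle [deg],
torsion rule).  Torsion rules:

* ``("... "fixed", value)`` -- frozen torsion (ring/branch geometry),
* ``"chi", k``              -- the torsion IS chi_k,
* ``"chi_offset", (k, off)``-- torsion = chi_k + off (branch atoms such as
  Leu CD2 or the second carboxylate oxygen).
"""

from __future__ import annotations

#: 3-letter -> 1-letter amino-acid codes (20 standard types)
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: residue types that carry at least one chi angle (all but Ala/Gly)
CHI_BEARING_TYPES = (
    "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: backbone heavy-atom names (Cbeta is chi-independent and treated as part
#: of the fixed frame for energies; Gly has no CB)
BACKBONE_ATOMS = ("N", "CA", "C", "O")
STRIPPED_ATOMS = ("N", "CA", "C", "O", "CB")

#: IUPAC chi-defining atom quadruplets per residue type
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [], "GLY": [],
}

def n_chis(residue_type: str) -> int:
    """Number of chi angles for a residue type (0 for Ala/Gly)."""
    return len(CHI_ATOMS[residue_type])

SIDE_CHAIN_TEMPLATES = {
    "ALA": [
        ("CB", "C", "C", "N", "CA", 1.5287, 109.471, "fixed", -120.020),
    ],
    "GLY": [],
    "ARG": [
        ("CB", "C", "C", "N", "CA", 1.5363, 111.550, "fixed", -123.561),
        ("CG", "C", "N", "CA", "CB", 1.5371, 114.536, "chi", 1),
        ("CD", "C", "CA", "CB", "CG", 1.5273, 112.417, "chi", 2),
        ("NE", "N", "CB", "CG", "CD", 1.4435, 111.016, "chi", 3),
        ("CZ", "C", "CG", "CD", "NE", 1.4058, 123.005, "chi", 4),
        ("NH1", "N", "CD", "NE", "CZ", 1.3906, 120.996, "fixed", 179.986),
        ("NH2", "N", "CD", "NE", "CZ", 1.3912, 119.815, "fixed", -0.012),
    ],
    "ASN": [
        ("CB", "C", "C", "N", "CA", 1.5309, 109.454, "fixed", -119.996),
        ("CG", "C", "N", "CA", "CB", 1.5066, 109.484, "chi", 1),
        ("OD1", "O", "CA", "CB", "CG", 1.2133, 119.974, "chi", 2),
        ("ND2", "N", "CA", "CB", "CG", 1.3476, 120.012, "chi_offset", (2, -179.926)),
    ],
    "ASP": [
        ("CB", "C", "C", "N", "CA", 1.5301, 109.480, "fixed", -120.011),
        ("CG", "C", "N", "CA", "CB", 1.5075, 109.463, "chi", 1),
        ("OD1", "O", "CA", "CB", "CG", 1.2080, 119.959, "chi", 2),
        ("OD2", "O", "CA", "CB", "CG", 1.3415, 119.999, "chi_offset", (2, -179.936)),
    ],
    "CYS": [
        ("CB", "C", "C", "N", "CA", 1.5285, 109.496, "fixed", -120.014),
        ("SG", "S", "N", "CA", "CB", 1.8141, 109.498, "chi", 1),
    ],
    "GLN": [
        ("CB", "C", "C", "N", "CA", 1.5288, 109.459, "fixed", -120.066),
        ("CG", "C", "N", "CA", "CB", 1.5284, 109.534, "chi", 1),
        ("CD", "C", "CA", "CB", "CG", 1.5066, 109.543, "chi", 2),
        ("OE1", "O", "CB", "CG", "CD", 1.2122, 119.937, "chi", 3),
        ("NE2", "N", "CB", "CG", "CD", 1.3471, 120.093, "chi_offset", (3, -179.957)),
    ],
    "GLU": [
        ("CB", "C", "C", "N", "CA", 1.5302, 109.482, "fixed", -119.956),
        ("CG", "C", "N", "CA", "CB", 1.5306, 109.402, "chi", 1),
        ("CD", "C", "CA", "CB", "CG", 1.5076, 109.430, "chi", 2),
        ("OE1", "O", "CB", "CG", "CD", 1.2084, 120.003, "chi", 3),
        ("OE2", "O", "CB", "CG", "CD", 1.3425, 119.998, "chi_offset", (3, -179.937)),
    ],
    "HIS": [
        ("CB", "C", "C", "N", "CA", 1.5337, 111.125, "fixed", -122.779),
        ("CG", "C", "N", "CA", "CB", 1.5100, 112.979, "chi", 1),
        ("ND1", "N", "CA", "CB", "CG", 1.3513, 120.329, "chi", 2),
        ("CD2", "C", "CA", "CB", "CG", 1.3376, 129.928, "chi_offset", (2, 179.846)),
        ("CE1", "C", "CB", "CG", "ND1", 1.3369, 107.862, "fixed", 179.905),
        ("NE2", "N", "CB", "CG", "CD2", 1.3739, 105.332, "fixed", -179.864),
    ],
    "ILE": [
        ("CB", "C", "C", "N", "CA", 1.5288, 109.430, "fixed", -120.073),
        ("CG1", "C", "N", "CA", "CB", 1.5294, 109.547, "chi", 1),
        ("CG2", "C", "N", "CA", "CB", 1.5303, 109.458, "chi_offset", (1, -119.972)),
        ("CD1", "C", "CA", "CB", "CG1", 1.5288, 109.547, "chi", 2),
    ],
    "LEU": [
        ("CB", "C", "C", "N", "CA", 1.5286, 109.416, "fixed", -119.973),
        ("CG", "C", "N", "CA", "CB", 1.5303, 109.495, "chi", 1),
        ("CD1", "C", "CA", "CB", "CG", 1.5300, 109.500, "chi", 2),
        ("CD2", "C", "CA", "CB", "CG", 1.5285, 109.501, "chi_offset", (2, 120.092)),
    ],
    "LYS": [
        ("CB", "C", "C", "N", "CA", 1.5300, 109.453, "fixed", -119.967),
        ("CG", "C", "N", "CA", "CB", 1.5307, 109.418, "chi", 1),
        ("CD", "C", "CA", "CB", "CG", 1.5308, 109.441, "chi", 2),
        ("CE", "C", "CB", "CG", "CD", 1.5291, 109.465, "chi", 3),
        ("NZ", "N", "CG", "CD", "CE", 1.4694, 109.500, "chi", 4),
    ],
    "MET": [
        ("CB", "C", "C", "N", "CA", 1.5294, 109.427, "fixed", -120.037),
        ("CG", "C", "N", "CA", "CB", 1.5284, 109.545, "chi", 1),
        ("SD", "S", "CA", "CB", "CG", 1.8137, 109.506, "chi", 2),
        ("CE", "C", "CB", "CG", "SD", 1.8135, 100.034, "chi", 3),
    ],
    "PHE": [
        ("CB", "C", "C", "N", "CA", 1.5289, 109.474, "fixed", -120.094),
        ("CG", "C", "N", "CA", "CB", 1.5052, 109.517, "chi", 1),
        ("CD1", "C", "CA", "CB", "CG", 1.3817, 120.058, "chi", 2),
        ("CD2", "C", "CA", "CB", "CG", 1.3832, 120.005, "chi_offset", (2, 179.757)),
        ("CE1", "C", "CB", "CG", "CD1", 1.3820, 120.029, "fixed", 179.994),
        ("CE2", "C", "CB", "CG", "CD2", 1.3819, 119.977, "fixed", 179.839),
        ("CZ", "C", "CG", "CD1", "CE1", 1.3806, 120.047, "fixed", -0.048),
    ],
    "PRO": [
        ("CB", "C", "C", "N", "CA", 1.5434, 104.722, "fixed", -118.841),
        ("CG", "C", "N", "CA", "CB", 1.5426, 105.059, "chi", 1),
        ("CD", "C", "CA", "CB", "CG", 1.5437, 105.063, "chi", 2),
    ],
    "SER": [
        ("CB", "C", "C", "N", "CA", 1.5287, 109.471, "fixed", -120.020),
        ("OG", "O", "N", "CA", "CB", 1.4283, 109.512, "chi", 1),
    ],
    "THR": [
        ("CB", "C", "C", "N", "CA", 1.5290, 109.412, "fixed", -120.000),
        ("OG1", "O", "N", "CA", "CB", 1.4280, 109.505, "chi", 1),
        ("CG2", "C", "N", "CA", "CB", 1.5301, 109.525, "chi_offset", (1, -120.031)),
    ],
    "TRP": [
        ("CB", "C", "C", "N", "CA", 1.5286, 109.523, "fixed", -120.026),
        ("CG", "C", "N", "CA", "CB", 1.5067, 109.442, "chi", 1),
        ("CD1", "C", "CA", "CB", "CG", 1.3426, 126.496, "chi", 2),
        ("CD2", "C", "CA", "CB", "CG", 1.4639, 126.512, "chi_offset", (2, 179.622)),
        ("NE1", "N", "CB", "CG", "CD1", 1.3686, 109.932, "fixed", 179.944),
        ("CE2", "C", "CB", "CG", "CD2", 1.4068, 106.076, "fixed", 179.958),
        ("CE3", "C", "CB", "CG", "CD2", 1.3961, 134.047, "fixed", 0.784),
        ("CZ2", "C", "CG", "CD2", "CE2", 1.3906, 119.346, "fixed", -179.825),
        ("CZ3", "C", "CG", "CD2", "CE3", 1.3659, 119.795, "fixed", 179.639),
        ("CH2", "C", "CD2", "CE2", "CZ2", 1.3773, 119.806, "fixed", 0.221),
    ],
    "TYR": [
        ("CB", "C", "C", "N", "CA", 1.5287, 109.470, "fixed", -120.041),
        ("CG", "C", "N", "CA", "CB", 1.5062, 109.497, "chi", 1),
        ("CD1", "C", "CA", "CB", "CG", 1.3823, 119.947, "chi", 2),
        ("CD2", "C", "CA", "CB", "CG", 1.3830, 119.943, "chi_offset", (2, 179.692)),
        ("CE1", "C", "CB", "CG", "CD1", 1.3810, 120.073, "fixed", -179.976),
        ("CE2", "C", "CB", "CG", "CD2", 1.3809, 120.020, "fixed", 179.775),
        ("CZ", "C", "CG", "CD1", "CE1", 1.3867, 119.978, "fixed", -0.102),
        ("OH", "O", "CD1", "CE1", "CZ", 1.3582, 120.130, "fixed", -179.966),
    ],
    "VAL": [
        ("CB", "C", "C", "N", "CA", 1.5287, 109.445, "fixed", -120.004),
        ("CG1", "C", "N", "CA", "CB", 1.5299, 109.509, "chi", 1),
        ("CG2", "C", "N", "CA", "CB", 1.5292, 109.490, "chi_offset", (1, 120.026)),
    ],
}


#: per-element Lennard-Jones parameters: contact radius r_i [angstrom] and
#: well depth eps_i; pairs combine as r_min = r_i + r_j, eps = sqrt(e_i e_j)
ELEMENT_LJ = {
    "C": (1.95, 0.10),
    "N": (1.82, 0.16),
    "O": (1.72, 0.20),
    "S": (2.05, 0.25),
}

#: additional intra-residue ring-closure bonds not implied by the Z-matrix
#: parent relation (used for bonded-pair exclusion counting)
RING_CLOSURE_BONDS = {
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

#: chi angles compared modulo 180 degrees (symmetric or commonly flipped
#: terminal groups); overridable at evaluation time
CHI_PERIODICITY_180 = {
    "ASP": (2,), "GLU": (3,), "PHE": (2,), "TYR": (2,),
    "ASN": (2,), "GLN": (3,), "HIS": (2,),
}

#: allowed side-chain atom relabelings for RMSD (applied as a whole set);
#: Asn/Gln/His amide- and imidazole-flip relabelings follow the common
#: "possibly flipped" convention
ATOM_SWAPS = {
    "ASP": [(("OD1", "OD2"),)],
    "GLU": [(("OE1", "OE2"),)],
    "PHE": [(("CD1", "CD2"), ("CE1", "CE2"))],
    "TYR": [(("CD1", "CD2"), ("CE1", "CE2"))],
    "ARG": [(("NH1", "NH2"),)],
    "ASN": [(("OD1", "ND2"),)],
    "GLN": [(("OE1", "NE2"),)],
    "HIS": [(("ND1", "CD2"), ("CE1", "NE2"))],
}


def element_of(atom_name: str) -> str:
    """Chemical element from a heavy-atom PDB name (C/N/O/S)."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
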