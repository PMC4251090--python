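"""Protein structure model: atoms, residues, PDB I/O and backbone dihedrals.

A deliberately small single-chain model.  Coordinates are in angstrom and
angles in degrees at every API boundary.  PDB parsing and writing are
delegated to :mod:`gemmi`; hydrogens are dropped on read and never generated
(all metrics in this package use heavy atoms only).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .chemistry import CHI_ATOMS, STRIPPED_ATOMS, THREE_TO_ONE, element_of
from .geometry import measure_dihedral

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "read_pdb",
    "write_pdb",
    "strip_side_chains",
    "measure_chis",
]


@dataclass
class Atom:
    """A heavy atom: PDB name, chemical element and position (angstrom)."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """One amino-acid residue with its atoms and backbone dihedrals.

    ``index`` is the 1-based position in the chain (report convention);
    ``phi``/``psi`` are in (-180, 180] or ``None`` at chain termini.
    """

    index: int
    type: str
    atoms: list[Atom] = field(default_factory=list)
    phi: float | None = None
    psi: float | None = None

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.type}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def pos(self, name: str) -> np.ndarray:
        return self.atom(name).position

    @property
    def side_chain_atoms(self) -> list[Atom]:
        """Heavy atoms beyond the backbone frame (CB exclusive)."""
        return [a for a in self.atoms if a.name not in STRIPPED_ATOMS]


@dataclass
class ProteinStructure:
    """An ordered single chain of residues."""

    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[r.type] for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "ProteinStructure":
        return copy.deepcopy(self)

    def compute_backbone_dihedrals(self) -> None:
        """Fill phi/psi for every residue (None at the respective terminus)."""
        rs = self.residues
        for i, r in enumerate(rs):
            r.phi = None
            r.psi = None
            if i > 0:
                r.phi = measure_dihedral(
                    rs[i - 1].pos("C"), r.pos("N"), r.pos("CA"), r.pos("C")
                )
            if i < len(rs) - 1:
                r.psi = measure_dihedral(
                    r.pos("N"), r.pos("CA"), r.pos("C"), rs[i + 1].pos("N")
                )


_REQUIRED_BACKBONE = ("N", "CA", "C")


def read_pdb(path, chain: str | None = None) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    The first model is used; ``chain`` selects a chain id (default: first
    protein chain).  Alternate locations are resolved by highest occupancy,
    hydrogens are discarded, and insertion codes are rejected.  Every residue
    must carry the N/CA/C backbone atoms; a residue missing one of them is
    reported by name (the packing pipeline treats it as a missing main-chain
    atom and refuses the input).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    st.remove_alternative_conformations()  # keeps highest occupancy
    model = st[0]
    sel = None
    for ch in model:
        if chain is None or ch.name == chain:
            sel = ch
            break
    if sel is None:
        raise ValueError(f"{path}: chain {chain!r} not found")

    residues: list[Residue] = []
    for i, gres in enumerate(sel):
        if gres.name not in THREE_TO_ONE:
            continue  # waters/ligands
        if gres.seqid.icode not in (" ", "\x00", ""):
            raise ValueError(
                f"residue {gres.name}{gres.seqid.num}: insertion codes unsupported"
            )
        atoms = []
        seen = set()
        for ga in gres:
            if ga.element.is_hydrogen:
                continue
            if ga.name in seen:
                continue
            seen.add(ga.name)
            atoms.append(
                Atom(ga.name, element_of(ga.name), [ga.pos.x, ga.pos.y, ga.pos.z])
            )
        res = Residue(index=len(residues) + 1, type=gres.name, atoms=atoms)
        for req in _REQUIRED_BACKBONE:
            if not res.has_atom(req):
                raise ValueError(
                    f"residue {gres.name}{gres.seqid.num}: missing main-chain atom {req}"
                )
        residues.append(res)
    if not residues:
        raise ValueError(f"{path}: no amino-acid residues in selected chain")
    structure = ProteinStructure(residues)
    structure.compute_backbone_dihedrals()
    return structure


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write the structure as standard ATOM records (occupancy 1.00)."""
    if len(structure) == 0:
        raise ValueError("cannot write an empty structure")
    st = gemmi.Structure()
    st.name = "antpack"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for res in structure.residues:
        gres = gemmi.Residue()
        gres.name = res.type
        gres.seqid = gemmi.SeqId(res.index, " ")
        gres.het_flag = "A"  # force ATOM records even for short chains
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = 1.0
            ga.b_iso = 0.0
            gres.add_atom(ga)
        ch.add_residue(gres)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def strip_side_chains(structure: ProteinStructure) -> ProteinStructure:
    """Return a copy retaining only N, CA, C, O (and CB where present).

    This prepares the fixed backbone on which side chains are repacked; the
    input structure is left untouched.  Idempotent.
    """
    out = structure.copy()
    for res in out.residues:
        res.atoms = [a for a in res.atoms if a.name in STRIPPED_ATOMS]
    return out


def measure_chis(residue: Residue) -> list[float]:
    """Measure the chi angles of a residue (empty for Ala/Gly), in degrees.

    Raises ``KeyError`` naming the first missing chi-defining atom.
    """
    quads = CHI_ATOMS[residue.type]
    chis = []
    for quad in quads:
        pts = []
        for name in quad:
            if not residue.has_atom(name):
                raise KeyError(
                    f"residue {residue.type}{residue.index}: "
                    f"missing chi-defining atom {name}"
                )
            pts.append(residue.pos(name))
        chis.append(measure_dihedral(*pts))
    return chis
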