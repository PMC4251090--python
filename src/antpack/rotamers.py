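"""Backbone-dependent rotamer sets and chi-driven side-chain construction.

A rotamer is a statistically favoured side-chain conformation given by its
chi-angle tuple and its observed frequency conditioned on the residue's
backbone (phi, psi) bin.  The library file format is a plain whitespace
table (one rotamer per line)::

    # residue  phi_centre  psi_centre  probability  chi1 [chi2 chi3 chi4]
    SER  -120  -120  0.50  -65.0

Only as many chi columns as the residue type defines are present.  An
importer for the widely used 2010 backbone-dependent library column layout
is provided (``load_dunbrack_library``); that data itself is not bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .chemistry import (
    CHI_BEARING_TYPES,
    SIDE_CHAIN_TEMPLATES,
    THREE_TO_ONE,
    n_chis,
)
from .geometry import place_atom, wrap_degrees
from .structure import Atom, ProteinStructure, Residue

__all__ = [
    "Rotamer",
    "RotamerSet",
    "RotamerLibrary",
    "load_library",
    "load_dunbrack_library",
    "toy_library_path",
    "rotamer_sets_for",
    "build_side_chain",
]

#: (phi, psi) bin used for termini where a backbone dihedral is undefined
DEFAULT_TERMINUS_BIN = (-60.0, -40.0)


@dataclass(frozen=True)
class Rotamer:
    """One candidate side-chain conformation within a rotamer set."""

    chis: tuple[float, ...]
    probability: float
    id: int  # 0-based index j within its set

    def __post_init__(self):
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("rotamer probability must lie in (0, 1]")


@dataclass
class RotamerSet:
    """Candidate rotamers for one packable residue, ordered by probability."""

    residue_index: int
    residue_type: str
    rotamers: list[Rotamer]

    def __post_init__(self):
        if not self.rotamers:
            raise ValueError("a rotamer set must contain at least one rotamer")

    def __len__(self) -> int:
        return len(self.rotamers)


class RotamerLibrary:
    """Rotamer records keyed by (residue type, phi bin, psi bin)."""

    def __init__(self, entries: dict, bin_width: float):
        if not entries:
            raise ValueError("empty rotamer library")
        self.entries = entries
        self.bin_width = float(bin_width)
        self._centres: dict[str, np.ndarray] = {}
        for rtype, phi_c, psi_c in entries:
            self._centres.setdefault(rtype, [])
        for rtype in self._centres:
            cs = sorted({(p, q) for (t, p, q) in entries if t == rtype})
            self._centres[rtype] = np.array(cs, dtype=float)

    @property
    def residue_types(self) -> set[str]:
        return set(self._centres)

    def lookup(self, residue_type: str, phi: float, psi: float) -> list[tuple]:
        """Records of the bin whose centre is nearest to (phi, psi).

        Distances are measured on the torus (360-degree wraparound in both
        backbone dihedrals).
        """
        if residue_type not in self._centres:
            raise KeyError(f"residue type {residue_type} absent from library")
        cs = self._centres[residue_type]
        dphi = np.abs(cs[:, 0] - wrap_degrees(phi))
        dpsi = np.abs(cs[:, 1] - wrap_degrees(psi))
        dphi = np.minimum(dphi, 360.0 - dphi)
        dpsi = np.minimum(dpsi, 360.0 - dpsi)
        k = int(np.argmin(dphi**2 + dpsi**2))
        centre = (cs[k, 0], cs[k, 1])
        return self.entries[(residue_type, centre[0], centre[1])]


def _parse_library_lines(lines, origin: str) -> RotamerLibrary:
    entries: dict = {}
    centres_phi = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        try:
            rtype = fields[0].upper()
            if rtype not in THREE_TO_ONE:
                raise ValueError(f"unknown residue type {rtype!r}")
            if rtype not in CHI_BEARING_TYPES:
                raise ValueError(f"residue type {rtype} carries no chi angles")
            k = n_chis(rtype)
            if len(fields) != 4 + k:
                raise ValueError(
                    f"expected {4 + k} fields for {rtype}, found {len(fields)}"
                )
            phi_c = wrap_degrees(float(fields[1]))
            psi_c = wrap_degrees(float(fields[2]))
            prob = float(fields[3])
            if not 0.0 < prob <= 1.0:
                raise ValueError(f"probability {prob} outside (0, 1]")
            chis = tuple(wrap_degrees(float(x)) for x in fields[4 : 4 + k])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{origin}, line {lineno}: {exc}") from exc
        entries.setdefault((rtype, phi_c, psi_c), []).append((chis, prob))
        centres_phi.add(phi_c)
    if not entries:
        raise ValueError(f"{origin}: no rotamer records found")
    # infer the bin width from distinct phi centres (single centre -> 360)
    cs = sorted(centres_phi)
    width = 360.0 if len(cs) < 2 else min(
        cs[i + 1] - cs[i] for i in range(len(cs) - 1)
    )
    return RotamerLibrary(entries, bin_width=width)


def load_library(path) -> RotamerLibrary:
    """Load a rotamer library from the documented plain-text format."""
    with open(path) as fh:
        return _parse_library_lines(fh, origin=str(path))


def load_dunbrack_library(path) -> RotamerLibrary:
    """Import a library in the 2010 backbone-dependent column layout.

    Columns: resname phi psi count r1 r2 r3 r4 probability chi1..chi4
    (chi standard deviations, if present, are ignored).  The user supplies
    the file; it is not distributed with this package.
    """
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 13:
                raise ValueError(f"{path}: unrecognised record: {line[:60]!r}")
            rtype = f[0].upper()
            if rtype not in CHI_BEARING_TYPES:
                continue
            k = n_chis(rtype)
            chis = " ".join(f[9 : 9 + k])
            lines.append(f"{rtype} {f[1]} {f[2]} {f[8]} {chis}")
    return _parse_library_lines(lines, origin=str(path))


def toy_library_path() -> str:
    """Path of the bundled coarse toy rotamer library."""
    return str(resources.files("antpack.data") / "toy_library.txt")


def rotamer_sets_for(
    structure: ProteinStructure,
    library: RotamerLibrary,
    prob_cutoff: float = 0.98,
) -> list[RotamerSet]:
    """Build one rotamer set per packable residue (Ala/Gly excluded).

    Rotamers are drawn from the library bin containing the residue's
    (phi, psi); termini with an undefined backbone dihedral fall back to the
    helical default bin.  Within a set, rotamers are sorted by descending
    probability (ties by ascending chi1) and truncated at ``prob_cutoff``
    cumulative probability (at least one rotamer is always kept).
    """
    sets = []
    for res in structure.residues:
        if res.type not in CHI_BEARING_TYPES:
            continue
        phi = res.phi if res.phi is not None else DEFAULT_TERMINUS_BIN[0]
        psi = res.psi if res.psi is not None else DEFAULT_TERMINUS_BIN[1]
        records = library.lookup(res.type, phi, psi)
        records = sorted(records, key=lambda rec: (-rec[1], rec[0][0]))
        kept = []
        cum = 0.0
        for chis, prob in records:
            if kept and cum >= prob_cutoff:
                break
            kept.append((chis, prob))
            cum += prob
        rotamers = [
            Rotamer(chis=chis, probability=p, id=j) for j, (chis, p) in enumerate(kept)
        ]
        sets.append(
            RotamerSet(residue_index=res.index, residue_type=res.type, rotamers=rotamers)
        )
    return sets


def build_side_chain(residue: Residue, residue_type: str, chis) -> Residue:
    """Place ideal-geometry side-chain heavy atoms for the given chi tuple.

    Atoms are constructed sequentially from internal coordinates (bond
    length, bond angle, torsion) relative to already placed atoms; each chi
    sets one proper dihedral.  Backbone atoms (N, CA, C, O) are copied
    bitwise; any existing side-chain atoms (CB included) are replaced.
    """
    chis = tuple(float(c) for c in chis)
    if len(chis) != n_chis(residue_type):
        raise ValueError(
            f"{residue_type} takes {n_chis(residue_type)} chi angles, got {len(chis)}"
        )
    for req in ("N", "CA", "C"):
        if not residue.has_atom(req):
            raise ValueError(f"residue {residue.index}: missing backbone atom {req}")

    new_atoms = [
        Atom(a.name, a.element, a.position.copy())
        for a in residue.atoms
        if a.name in ("N", "CA", "C", "O")
    ]
    positions = {a.name: a.position for a in new_atoms}
    for row in SIDE_CHAIN_TEMPLATES[residue_type]:
        name, elem, ra, rb, rc, length, angle, kind, value = row
        if kind == "chi":
            torsion = chis[value - 1]
        elif kind == "chi_offset":
            k, off = value
            torsion = chis[k - 1] + off
        else:
            torsion = value
        pos = place_atom(positions[ra], positions[rb], positions[rc], length, angle, torsion)
        positions[name] = pos
        new_atoms.append(Atom(name, elem, pos))

    return Residue(
        index=residue.index,
        type=residue_type,
        atoms=new_atoms,
        phi=residue.phi,
        psi=residue.psi,
    )
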