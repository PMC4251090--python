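"""Synthetic test instances and the exhaustive-enumeration oracle.

Instances come in two flavours:

* *synthetic-table* instances (:func:`make_random_instance`,
  :func:`make_planted_instance`): a real ideal-geometry backbone plus
  rotamer sets, but with interaction tables drawn from simple random
  distributions.  They exercise the combinatorial search in isolation and
  are small enough for the brute-force oracle.
* *library* instances (:func:`make_library_instance`): rotamer sets from
  the bundled toy library and physically computed interaction tables, for
  end-to-end packing and continuous-minimisation tests.

The enumeration oracle is the ground truth every search result is compared
against: it evaluates every assignment and returns the exact global
minimiser (ties resolved to the lexicographically smallest choice vector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aco import Assignment
from .chemistry import ONE_TO_THREE, n_chis
from .energy import (
    InteractionTables,
    ScoreFunction,
    build_interaction_tables,
    builtin_score_functions,
    total_energy,
)
from .geometry import place_atom, wrap_degrees
from .rotamers import (
    Rotamer,
    RotamerSet,
    build_side_chain,
    load_library,
    rotamer_sets_for,
    toy_library_path,
)
from .structure import Atom, ProteinStructure, Residue

__all__ = [
    "ToyInstance",
    "make_backbone",
    "make_random_instance",
    "make_planted_instance",
    "make_library_instance",
    "enumerate_optimum",
]

ENUMERATION_GUARD = 10**6

# ideal backbone internal coordinates (angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_GEOMETRIES = {"helix": (-60.0, -45.0), "strand": (-120.0, 120.0)}


@dataclass
class ToyInstance:
    """A packing instance with everything the search and oracle need."""

    structure: ProteinStructure
    rotamer_sets: list[RotamerSet]
    tables: InteractionTables
    planted_optimum: Assignment | None = None
    native: ProteinStructure | None = None


def make_backbone(n: int, geometry: str = "helix", sequence: str | None = None) -> ProteinStructure:
    """Deterministic ideal-geometry backbone (N, CA, C, O, CB per residue).

    ``geometry`` sets uniform backbone dihedrals: (phi, psi) = (-60, -45)
    for a helix, (-120, 120) for a strand.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if geometry not in _GEOMETRIES:
        raise ValueError(f"geometry must be one of {sorted(_GEOMETRIES)}")
    if sequence is None:
        sequence = ("SLVTKDEM" * (n // 8 + 1))[:n]
    if len(sequence) != n:
        raise ValueError("sequence length must equal n")
    types = []
    for ch in sequence.upper():
        if ch not in ONE_TO_THREE:
            raise ValueError(f"invalid amino-acid letter {ch!r}")
        types.append(ONE_TO_THREE[ch])

    phi, psi = _GEOMETRIES[geometry]
    residues: list[Residue] = []
    # first residue in a canonical frame
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    theta = np.radians(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    frames = [(N, CA, C)]
    for _ in range(1, n):
        Np, CAp, Cp = frames[-1]
        Nn = place_atom(Np, CAp, Cp, _B_C_N, _A_CA_C_N, psi)
        CAn = place_atom(CAp, Cp, Nn, _B_N_CA, _A_C_N_CA, 180.0)  # trans omega
        Cn = place_atom(Cp, Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
        frames.append((Nn, CAn, Cn))
    for i, (rtype, (Ni, CAi, Ci)) in enumerate(zip(types, frames)):
        O = place_atom(Ni, CAi, Ci, _B_C_O, _A_CA_C_O, psi - 180.0)
        atoms = [
            Atom("N", "N", Ni),
            Atom("CA", "C", CAi),
            Atom("C", "C", Ci),
            Atom("O", "O", O),
        ]
        res = Residue(index=i + 1, type=rtype, atoms=atoms)
        if rtype != "GLY":
            res = build_side_chain(res, rtype, [0.0] * n_chis(rtype))
            res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
        residues.append(res)
    structure = ProteinStructure(residues)
    structure.compute_backbone_dihedrals()
    return structure


def _synthetic_rotamer_sets(structure: ProteinStructure, m: int, rng) -> list[RotamerSet]:
    """m rotamers per packable residue with well-separated chi1 values."""
    sets = []
    probs = np.arange(m, 0, -1, dtype=float)
    probs /= probs.sum()
    for res in structure.residues:
        k = n_chis(res.type)
        if k == 0:
            continue
        rots = []
        for j in range(m):
            chi1 = wrap_degrees(-180.0 + (j + 0.5) * 360.0 / m + rng.uniform(-5, 5))
            chis = (chi1,) + tuple(
                wrap_degrees(rng.choice([-60.0, 60.0, 180.0]) + rng.uniform(-5, 5))
                for _ in range(k - 1)
            )
            rots.append(Rotamer(chis=chis, probability=float(probs[j]), id=j))
        sets.append(RotamerSet(res.index, res.type, rots))
    return sets


def _check_guard(sizes):
    states = int(np.prod([float(m) for m in sizes]))
    if np.prod([float(m) for m in sizes]) > ENUMERATION_GUARD:
        raise ValueError(
            f"state space {states} exceeds the enumeration guard {ENUMERATION_GUARD}"
        )


def make_random_instance(
    n: int, m: int, pair_density: float, seed: int
) -> ToyInstance:
    """Seeded random instance: self energies U[0,5], pair energies U[-1,1]
    present with probability ``pair_density``.  Reproducible bit-for-bit."""
    rng = np.random.default_rng(seed)
    structure = make_backbone(n, "helix")
    sets = _synthetic_rotamer_sets(structure, m, rng)
    _check_guard([m] * len(sets))
    self_e = [rng.uniform(0.0, 5.0, size=m) for _ in sets]
    pair_e = {}
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            if rng.random() < pair_density:
                pair_e[(a, b)] = rng.uniform(-1.0, 1.0, size=(m, m))
    tables = InteractionTables(self_energy=self_e, pair_energy=pair_e)
    return ToyInstance(structure, sets, tables)


def make_planted_instance(n: int, m: int, margin: float, seed: int) -> ToyInstance:
    """Random instance with a designated assignment implanted as the unique
    global optimum, with an energy gap of at least ``margin`` over the
    runner-up (verified by enumeration at construction).  The planted
    rotamers are also materialised as a native structure so that packing
    followed by evaluation closes the loop."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    inst = make_random_instance(n, m, pair_density=0.5, seed=seed)
    rng = np.random.default_rng(seed + 1)
    planted = np.array([rng.integers(len(s)) for s in inst.rotamer_sets])

    # a uniform shift of delta on every planted self energy raises the gap to
    # any other assignment by at least delta (it shares at most n-1 choices)
    gap0 = _planted_gap(inst.tables, planted, 0.0)
    delta = max(0.0, margin - gap0)
    for i, j in enumerate(planted):
        inst.tables.self_energy[i][j] -= delta

    opt = enumerate_optimum(inst.tables)
    assert np.array_equal(opt.choices, planted), "planting failed verification"
    gap = _planted_gap(inst.tables, planted, 0.0)
    assert gap >= margin - 1e-9

    native = inst.structure.copy()
    by_index = {r.index: r for r in native.residues}
    for rset, j in zip(inst.rotamer_sets, planted):
        res = by_index[rset.residue_index]
        rebuilt = build_side_chain(res, rset.residue_type, rset.rotamers[j].chis)
        res.atoms = rebuilt.atoms
    inst.planted_optimum = Assignment(planted, total_energy(planted, inst.tables))
    inst.native = native
    return inst


def _planted_gap(tables: InteractionTables, planted, delta: float) -> float:
    """Exact energy gap between the planted assignment (with ``delta``
    subtracted from each of its self energies) and the best other state."""
    E = _energy_tensor(tables)
    if delta != 0.0:
        for i, j in enumerate(planted):
            idx = [slice(None)] * E.ndim
            idx[i] = j
            E[tuple(idx)] -= delta
    p_idx = tuple(planted)
    e_planted = E[p_idx]
    E[p_idx] = np.inf
    return float(E.min() - e_planted)


def make_library_instance(
    n: int,
    geometry: str = "helix",
    score_function: ScoreFunction | None = None,
    sequence: str | None = None,
) -> ToyInstance:
    """Physically scored instance from the bundled toy rotamer library."""
    structure = make_backbone(n, geometry, sequence)
    library = load_library(toy_library_path())
    sets = rotamer_sets_for(structure, library)
    sf = score_function or builtin_score_functions(1)[0]
    tables = build_interaction_tables(structure, sets, sf)
    return ToyInstance(structure, sets, tables)


def _energy_tensor(tables: InteractionTables) -> np.ndarray:
    sizes = tables.sizes
    _check_guard(sizes)
    n = len(sizes)
    E = np.zeros(sizes)
    for i, se in enumerate(tables.self_energy):
        shape = [1] * n
        shape[i] = len(se)
        E += np.asarray(se).reshape(shape)
    for (a, b), mat in tables.pair_energy.items():
        shape = [1] * n
        shape[a], shape[b] = mat.shape
        E += np.asarray(mat).reshape(shape)
    return E


def enumerate_optimum(tables: InteractionTables) -> Assignment:
    """Exact global minimiser by exhaustive enumeration (the oracle).

    Guarded to at most 10^6 states; ties resolve to the lexicographically
    smallest choice vector (first minimum in row-major order).
    """
    E = _energy_tensor(tables)
    flat_idx = int(np.argmin(E))
    choices = np.array(np.unravel_index(flat_idx, E.shape))
    return Assignment(choices, float(E.ravel()[flat_idx]))
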