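"""Pluggable weighted-term energies and precomputed rotamer interaction tables.

The packing search only requires *k* distinct, deterministic, finite energy
functions; the ones provided combine a soft Lennard-Jones pair potential
(attractive and capped repulsive branches scored separately, so their
weights can differ) with a rotamer-statistics term derived from library
frequencies.  Constant backbone-backbone contributions are excluded
throughout: the search ranks side-chain placements, so side-chain
independent terms are ruled out of the tables.

Energies are unitless scores.  Atom-pair interactions are switched smoothly
to zero at a short cutoff so that continuous chi minimisation sees
continuous gradients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chemistry import ELEMENT_LJ, RING_CLOSURE_BONDS, SIDE_CHAIN_TEMPLATES
from .rotamers import Rotamer, RotamerSet, build_side_chain
from .structure import ProteinStructure, Residue

__all__ = [
    "lj_attractive",
    "lj_repulsive",
    "rotamer_statistics_term",
    "ScoreFunction",
    "builtin_score_functions",
    "InteractionTables",
    "build_interaction_tables",
    "total_energy",
]

#: atom-pair distance cutoff (angstrom) and switching width
ATOM_CUTOFF = 6.0
SWITCH_WIDTH = 0.5
#: default residue-pair cutoff on Cbeta-Cbeta distance (Calpha for Gly)
PAIR_CUTOFF = 10.0
#: default cap on the repulsive branch per atom pair (soft clash)
REP_CAP = 10.0


def lj_attractive(r, r_min, eps):
    """Attractive branch of the 12-6 potential: 0 inside the well minimum,
    ``eps * ((r_min/r)**12 - 2 (r_min/r)**6)`` (which is <= 0) outside."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    x = r_min / r
    val = eps * (x**12 - 2.0 * x**6)
    out = np.where(r < r_min, 0.0, np.minimum(val, 0.0))
    return out if out.shape else float(out)


def lj_repulsive(r, r_min, cap):
    """Soft repulsive branch: 0 for r >= r_min; inside the well the unit-depth
    12-6 excess ``(r_min/r)**12 - 2 (r_min/r)**6 + 1`` rises from 0 at r_min
    and is capped at ``cap``, so the output lies in [0, cap]; r = 0 returns
    the cap (a soft clash penalty rather than a hard wall)."""
    r = np.asarray(r, dtype=float)
    pos = r > 0
    # unit well depth for the shape; the cap bounds the clash penalty
    with np.errstate(over="ignore", invalid="ignore"):
        x = np.where(pos, r_min / np.where(pos, r, 1.0), np.inf)
        val = np.where(pos, (x**12 - 2.0 * x**6) + 1.0, np.inf)
    out = np.where(r >= r_min, 0.0, np.minimum(val, cap))
    return out if out.shape else float(out)


def rotamer_statistics_term(rotamer: Rotamer, rset: RotamerSet) -> float:
    """Internal rotamer preference from library statistics:
    ``-ln(p_j / p_max)``; zero for the set's most probable rotamer."""
    p_max = max(r.probability for r in rset.rotamers)
    return float(-np.log(rotamer.probability / p_max))


@dataclass(frozen=True)
class ScoreFunction:
    """A weighted sum of energy terms, owned by one colony/thread."""

    id: int
    weights: dict = field(
        default_factory=lambda: {"lj_atr": 1.0, "lj_rep": 0.55, "rot_stat": 0.7}
    )

    def __post_init__(self):
        ws = list(self.weights.values())
        if not ws or not any(w != 0 for w in ws):
            raise ValueError("score function needs at least one nonzero weight")
        if not all(np.isfinite(w) for w in ws):
            raise ValueError("score-function weights must be finite")


#: eight preset weight maps (lj_atr, lj_rep, rot_stat); they vary the balance
#: between packing tightness, clash avoidance and library statistics the way
#: a panel of distinct score functions would
_PRESETS = [
    (1.00, 0.55, 0.70),
    (0.80, 1.00, 0.50),
    (1.20, 0.40, 0.90),
    (0.60, 0.80, 1.20),
    (1.00, 1.00, 1.00),
    (1.40, 0.30, 0.40),
    (0.50, 1.20, 0.80),
    (0.90, 0.70, 0.30),
]


def builtin_score_functions(k: int) -> list[ScoreFunction]:
    """Return ``k`` distinct preset score functions (1 <= k <= 8)."""
    if not 1 <= k <= len(_PRESETS):
        raise ValueError(f"k must be in [1, {len(_PRESETS)}]")
    return [
        ScoreFunction(id=g, weights={"lj_atr": a, "lj_rep": r, "rot_stat": s})
        for g, (a, r, s) in enumerate(_PRESETS[:k])
    ]


# ---------------------------------------------------------------------------
# atom-pair machinery


def _switch(r):
    """C1 switching function: 1 below cutoff-width, 0 above cutoff."""
    s = np.clip((r - (ATOM_CUTOFF - SWITCH_WIDTH)) / SWITCH_WIDTH, 0.0, 1.0)
    return 1.0 - s * s * (3.0 - 2.0 * s)


def pair_lj_energy(coords_a, elems_a, coords_b, elems_b, weights, rep_cap=REP_CAP):
    """Weighted LJ energy between two atom groups (no exclusions)."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0.0
    ca = np.asarray(coords_a)
    cb = np.asarray(coords_b)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    ra = np.array([ELEMENT_LJ[e][0] for e in elems_a])
    rb = np.array([ELEMENT_LJ[e][0] for e in elems_b])
    ea = np.array([ELEMENT_LJ[e][1] for e in elems_a])
    eb = np.array([ELEMENT_LJ[e][1] for e in elems_b])
    rmin = ra[:, None] + rb[None, :]
    eps = np.sqrt(ea[:, None] * eb[None, :])
    d = np.maximum(d, 1e-6)
    atr = lj_attractive(d, rmin, eps)
    rep = lj_repulsive(d, rmin, rep_cap)
    sw = _switch(d)
    return float(
        np.sum(sw * (weights.get("lj_atr", 0.0) * atr + weights.get("lj_rep", 0.0) * rep))
    )


def _bond_graph(residue_type: str) -> dict:
    """Intra-residue heavy-atom bond adjacency (backbone + template + rings)."""
    adj: dict[str, set[str]] = {n: set() for n in ("N", "CA", "C", "O")}
    for a, b in (("N", "CA"), ("CA", "C"), ("C", "O")):
        adj[a].add(b)
        adj[b].add(a)
    for row in SIDE_CHAIN_TEMPLATES.get(residue_type, []):
        name, _, _, _, parent = row[0], row[1], row[2], row[3], row[4]
        adj.setdefault(name, set())
        adj.setdefault(parent, set())
        adj[name].add(parent)
        adj[parent].add(name)
    for a, b in RING_CLOSURE_BONDS.get(residue_type, []):
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bond_separation(residue_type: str, name_a: str, name_b: str, limit: int = 4) -> int:
    """Bond-count distance between two atoms of one residue (BFS, capped)."""
    if name_a == name_b:
        return 0
    adj = _bond_graph(residue_type)
    if name_a not in adj or name_b not in adj:
        return limit + 1
    frontier = {name_a}
    seen = {name_a}
    for depth in range(1, limit + 1):
        frontier = {n for cur in frontier for n in adj[cur]} - seen
        if name_b in frontier:
            return depth
        seen |= frontier
    return limit + 1


@dataclass
class InteractionTables:
    """Precomputed self and pairwise rotamer energies for one score function.

    ``self_energy[i][j]``: rotamer j at packable residue i against the fixed
    backbone plus its internal statistics term.  ``pair_energy[(a, b)]``
    (a < b, indices into the packable-residue list): matrix of interaction
    energies between the side chains of the two residues; residue pairs
    beyond the Cbeta cutoff are absent, meaning exactly zero.
    """

    self_energy: list[np.ndarray]
    pair_energy: dict[tuple[int, int], np.ndarray]
    neighbors: list[list] = field(default_factory=list)

    def __post_init__(self):
        if not self.neighbors:
            self.neighbors = [[] for _ in self.self_energy]
            for (a, b), mat in self.pair_energy.items():
                self.neighbors[a].append((b, mat))
                self.neighbors[b].append((a, mat.T))

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.self_energy]

    def pair(self, a: int, b: int, ja: int, jb: int) -> float:
        """Symmetric access; absent pairs are exactly 0."""
        if a > b:
            a, b, ja, jb = b, a, jb, ja
        mat = self.pair_energy.get((a, b))
        return 0.0 if mat is None else float(mat[ja, jb])


def _backbone_frame_atoms(res: Residue):
    coords, elems, names = [], [], []
    for a in res.atoms:
        if a.name in ("N", "CA", "C", "O", "CB"):
            coords.append(a.position)
            elems.append(a.element)
            names.append(a.name)
    return coords, elems, names


def _side_chain_atoms(res: Residue):
    coords, elems, names = [], [], []
    for a in res.atoms:
        if a.name not in ("N", "CA", "C", "O", "CB"):
            coords.append(a.position)
            elems.append(a.element)
            names.append(a.name)
    return coords, elems, names


def _anchor_position(res: Residue) -> np.ndarray:
    """Cbeta position (Calpha for Gly / residues without CB)."""
    return res.pos("CB") if res.has_atom("CB") else res.pos("CA")


def self_energy_of_placement(
    structure: ProteinStructure,
    res_pos: int,
    placed: Residue,
    weights: dict,
    rep_cap: float = REP_CAP,
) -> float:
    """LJ energy of one placed side chain against every backbone frame.

    Intra-residue atom pairs separated by three bonds or fewer are excluded;
    the statistics term is *not* included here.
    """
    sc_coords, sc_elems, sc_names = _side_chain_atoms(placed)
    if not sc_coords:
        return 0.0
    total = 0.0
    for k, other in enumerate(structure.residues):
        bb_coords, bb_elems, bb_names = _backbone_frame_atoms(other)
        if k == res_pos:
            # within the same residue, pairs separated by <= 3 bonds are excluded
            for sc_c, sc_e, sc_n in zip(sc_coords, sc_elems, sc_names):
                for bb_c, bb_e, bb_n in zip(bb_coords, bb_elems, bb_names):
                    if bond_separation(placed.type, sc_n, bb_n) > 3:
                        total += pair_lj_energy(
                            [sc_c], [sc_e], [bb_c], [bb_e], weights, rep_cap
                        )
            continue
        total += pair_lj_energy(sc_coords, sc_elems, bb_coords, bb_elems, weights, rep_cap)
    return total


def build_interaction_tables(
    structure: ProteinStructure,
    rotamer_sets: list[RotamerSet],
    score_function: ScoreFunction,
    cutoff: float = PAIR_CUTOFF,
    rep_cap: float = REP_CAP,
) -> InteractionTables:
    """Precompute self and pair energies for every rotamer of every set.

    Self energies: backbone-interaction LJ plus the weighted statistics
    term.  Pair energies: LJ between side-chain heavy atoms of the two
    rotamers; residue pairs whose anchor (Cbeta) distance exceeds ``cutoff``
    are omitted.  Constant backbone-backbone terms never enter.
    """
    if not rotamer_sets:
        raise ValueError("rotamer sets must be nonempty")
    w = score_function.weights
    res_by_index = {r.index: (pos, r) for pos, r in enumerate(structure.residues)}

    built: list[list[Residue]] = []
    self_e: list[np.ndarray] = []
    for rset in rotamer_sets:
        pos, res = res_by_index[rset.residue_index]
        placements = [
            build_side_chain(res, rset.residue_type, rot.chis) for rot in rset.rotamers
        ]
        energies = np.array(
            [
                self_energy_of_placement(structure, pos, placed, w, rep_cap)
                + w.get("rot_stat", 0.0) * rotamer_statistics_term(rot, rset)
                for rot, placed in zip(rset.rotamers, placements)
            ]
        )
        built.append(placements)
        self_e.append(energies)

    pair_e: dict[tuple[int, int], np.ndarray] = {}
    anchors = [
        _anchor_position(res_by_index[rset.residue_index][1]) for rset in rotamer_sets
    ]
    for a, b in itertools.combinations(range(len(rotamer_sets)), 2):
        if np.linalg.norm(anchors[a] - anchors[b]) > cutoff:
            continue
        mat = np.zeros((len(built[a]), len(built[b])))
        for ja, pa in enumerate(built[a]):
            ca, ea, _ = _side_chain_atoms(pa)
            for jb, pb in enumerate(built[b]):
                cb, eb, _ = _side_chain_atoms(pb)
                mat[ja, jb] = pair_lj_energy(ca, ea, cb, eb, w, rep_cap)
        if np.any(mat != 0.0):
            pair_e[(a, b)] = mat
    return InteractionTables(self_energy=self_e, pair_energy=pair_e)


def total_energy(choices, tables: InteractionTables) -> float:
    """Energy of a complete assignment:
    ``sum_i self[i][c_i] + sum_{a<b} pair[(a,b)][c_a][c_b]``."""
    choices = np.asarray(choices, dtype=int)
    if choices.shape[0] != len(tables.self_energy):
        raise ValueError(
            f"assignment has {choices.shape[0]} choices for "
            f"{len(tables.self_energy)} packable residues"
        )
    e = 0.0
    for i, j in enumerate(choices):
        e += float(tables.self_energy[i][j])
    for (a, b), mat in tables.pair_energy.items():
        e += float(mat[choices[a], choices[b]])
    return e
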