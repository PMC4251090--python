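"""Continuous chi-space refinement of placed rotamers ("subrotamers").

Library rotamers are discrete; a subrotamer is the result of gradient
minimisation of a placed rotamer's chi angles in its current structural
context, bounded to a small box around the parent so it stays attributable
to it.  Minimised variants are remembered per (residue, rotamer): the
subrotamer set starts as {r_j} and grows as

    A'   = {min(r_j), r_j}
    A^n  = {min(RandomP(A^{n-1})), A^{n-1}}

where RandomP is a uniform pick over the current members and a minimised
variant is kept only when it lowers the energy.  The primary rotamer is
always the last member; new subrotamers are prepended.

Three packing models build on this:

* model 1 -- each ant placement may be replaced by a subrotamer, minimised
  in the context of the residues the ant has already placed;
* model 2 -- model 1 followed by a final cyclic all-residue minimisation of
  the best assignment;
* model 3 -- plain discrete search followed by the final minimisation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .aco import Assignment, Colony, construct_assignment
from .energy import (
    InteractionTables,
    ScoreFunction,
    _anchor_position,
    _side_chain_atoms,
    pair_lj_energy,
    rotamer_statistics_term,
    self_energy_of_placement,
    total_energy,
    PAIR_CUTOFF,
    REP_CAP,
)
from .rotamers import RotamerSet, build_side_chain
from .structure import ProteinStructure

__all__ = [
    "Subrotamer",
    "SubrotamerSet",
    "minimize_chis",
    "extend_subrotamers",
    "ContinuousContext",
    "MinimisingColony",
    "MinimisationConfig",
]


@dataclass(frozen=True)
class MinimisationConfig:
    """Tunables of the continuous refinement."""

    max_deviation: float = 15.0  # degrees, box half-width around the parent
    max_subrotamers: int = 8
    accept_tol: float = 1e-9
    max_fun_evals: int = 60

    def __post_init__(self):
        if self.max_deviation < 0:
            raise ValueError("max_deviation must be >= 0")
        if self.max_subrotamers < 1:
            raise ValueError("max_subrotamers must be >= 1")


@dataclass(frozen=True)
class Subrotamer:
    """A minimised chi variant remembered alongside its parent rotamer."""

    parent: int  # parent rotamer id j
    chis: tuple[float, ...]
    energy_at_creation: float


class SubrotamerSet:
    """Ordered members for one (residue, rotamer); primary rotamer last."""

    def __init__(self, parent_id: int, parent_chis, max_size: int = 8):
        self.parent_id = parent_id
        self.parent_chis = tuple(float(c) for c in parent_chis)
        self.max_size = max_size
        self.members: list[Subrotamer] = [
            Subrotamer(parent_id, self.parent_chis, float("nan"))
        ]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def primary(self) -> Subrotamer:
        return self.members[-1]

    def prepend(self, sub: Subrotamer) -> None:
        self.members.insert(0, sub)
        if len(self.members) > self.max_size:
            # drop the oldest non-primary member
            del self.members[-2]


def minimize_chis(
    energy_fn,
    start_chis,
    max_deviation: float = 15.0,
    center_chis=None,
    max_fun_evals: int = 60,
) -> tuple[tuple[float, ...], float]:
    """Bounded quasi-Newton descent of an energy over a chi vector.

    ``energy_fn(chis) -> float`` is minimised with L-BFGS-B (gradients by
    finite differences; the energy terms are smooth by construction thanks
    to the switched cutoffs), with each chi constrained to
    ``center +- max_deviation`` (``center`` defaults to the start).  The
    returned energy is never above the starting energy.
    """
    x0 = np.asarray(start_chis, dtype=float)
    e0 = float(energy_fn(x0))
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at the starting chi vector")
    if max_deviation == 0.0 or x0.size == 0:
        return tuple(x0), e0
    centre = x0 if center_chis is None else np.asarray(center_chis, dtype=float)
    bounds = [(c - max_deviation, c + max_deviation) for c in centre]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = _scipy_minimize(
        energy_fn,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        jac="3-point",
        options={"maxfun": max_fun_evals, "ftol": 1e-12, "gtol": 1e-10},
    )
    e1 = float(res.fun)
    if e1 <= e0:
        return tuple(float(v) for v in res.x), e1
    return tuple(float(v) for v in np.asarray(start_chis, dtype=float)), e0


def extend_subrotamers(
    sset: SubrotamerSet,
    energy_fn,
    rng: np.random.Generator,
    config: MinimisationConfig = MinimisationConfig(),
) -> Subrotamer:
    """One growth step of a subrotamer set; returns the member placed.

    A member is picked uniformly at random, minimised in context (bounded to
    the box around the *primary* rotamer); if the minimised variant lowers
    the energy by more than ``accept_tol`` it is prepended and used,
    otherwise the picked member is used and the set is unchanged.
    """
    pick = sset.members[int(rng.integers(len(sset.members)))]
    chis, e1 = minimize_chis(
        energy_fn,
        pick.chis,
        max_deviation=config.max_deviation,
        center_chis=sset.parent_chis,
        max_fun_evals=config.max_fun_evals,
    )
    e_pick = float(energy_fn(np.asarray(pick.chis)))
    if e1 < e_pick - config.accept_tol:
        sub = Subrotamer(sset.parent_id, chis, e1)
        sset.prepend(sub)
        return sub
    return pick


class ContinuousContext:
    """Continuous energy evaluation of side-chain placements on a backbone.

    Mirrors the interaction tables exactly at library chi values: self
    energies against all backbone frames (same bonded exclusions), the
    library statistics term for the parent rotamer, and pair interactions
    only between residues whose anchor atoms lie within the pair cutoff.
    """

    def __init__(
        self,
        structure: ProteinStructure,
        rotamer_sets: list[RotamerSet],
        score_function: ScoreFunction,
        cutoff: float = PAIR_CUTOFF,
        rep_cap: float = REP_CAP,
    ):
        self.structure = structure
        self.rotamer_sets = rotamer_sets
        self.weights = score_function.weights
        self.rep_cap = rep_cap
        by_index = {r.index: (pos, r) for pos, r in enumerate(structure.residues)}
        self.res_pos = [by_index[s.residue_index][0] for s in rotamer_sets]
        self.residues = [by_index[s.residue_index][1] for s in rotamer_sets]
        anchors = [_anchor_position(r) for r in self.residues]
        n = len(rotamer_sets)
        self.neighbor_ids: list[list[int]] = [[] for _ in range(n)]
        for a in range(n):
            for b in range(a + 1, n):
                if np.linalg.norm(anchors[a] - anchors[b]) <= cutoff:
                    self.neighbor_ids[a].append(b)
                    self.neighbor_ids[b].append(a)
        # current placements: (parent rotamer id, chis, sc coords, sc elements)
        self.placed: list[tuple | None] = [None] * n

    def clear(self) -> None:
        self.placed = [None] * len(self.placed)

    def _build(self, i: int, chis):
        res = build_side_chain(
            self.residues[i], self.rotamer_sets[i].residue_type, chis
        )
        coords, elems, _ = _side_chain_atoms(res)
        return res, np.asarray(coords), elems

    def set_placement(self, i: int, parent_id: int, chis) -> None:
        _, coords, elems = self._build(i, chis)
        self.placed[i] = (parent_id, tuple(float(c) for c in chis), coords, elems)

    def _stat_const(self, i: int, parent_id: int) -> float:
        rset = self.rotamer_sets[i]
        return self.weights.get("rot_stat", 0.0) * rotamer_statistics_term(
            rset.rotamers[parent_id], rset
        )

    def local_energy(self, i: int, chis, parent_id: int) -> float:
        """Energy of residue i placed at ``chis``: backbone self energy,
        the parent's statistics term, and pairs to currently placed
        neighbours (other residues fixed)."""
        placed_res, coords, elems = self._build(i, chis)
        e = self_energy_of_placement(
            self.structure, self.res_pos[i], placed_res, self.weights, self.rep_cap
        )
        e += self._stat_const(i, parent_id)
        for b in self.neighbor_ids[i]:
            if self.placed[b] is not None:
                _, _, cb, eb = self.placed[b]
                e += pair_lj_energy(coords, elems, cb, eb, self.weights, self.rep_cap)
        return e

    def energy_fn(self, i: int, parent_id: int):
        return lambda chis: self.local_energy(i, chis, parent_id)

    def total(self) -> float:
        """Total energy of the complete current placement (all residues)."""
        if any(p is None for p in self.placed):
            raise ValueError("incomplete placement")
        e = 0.0
        for i, (parent_id, chis, coords, elems) in enumerate(self.placed):
            res, _, _ = self._build(i, chis)
            e += self_energy_of_placement(
                self.structure, self.res_pos[i], res, self.weights, self.rep_cap
            )
            e += self._stat_const(i, parent_id)
            for b in self.neighbor_ids[i]:
                if b > i:
                    _, _, cb, eb = self.placed[b]
                    e += pair_lj_energy(coords, elems, cb, eb, self.weights, self.rep_cap)
        return e

    def apply_assignment(self, assignment: Assignment) -> None:
        """Place every residue from an assignment (subrotamer chis when
        present, otherwise the library rotamer's chis)."""
        chis_list = getattr(assignment, "chis", None)
        for i, j in enumerate(assignment.choices):
            chis = (
                chis_list[i]
                if chis_list is not None
                else self.rotamer_sets[i].rotamers[j].chis
            )
            self.set_placement(i, int(j), chis)

    def global_minimise(
        self,
        config: MinimisationConfig = MinimisationConfig(),
        max_sweeps: int = 10,
        sweep_tol: float = 1e-6,
    ) -> float:
        """Cyclic coordinate minimisation over all placed residues.

        Each sweep applies :func:`minimize_chis` to every residue in turn
        (box centred on its parent rotamer); stops when a sweep improves the
        total by less than ``sweep_tol`` or after ``max_sweeps``."""
        e_prev = self.total()
        for _ in range(max_sweeps):
            for i in range(len(self.placed)):
                parent_id, chis, _, _ = self.placed[i]
                parent_chis = self.rotamer_sets[i].rotamers[parent_id].chis
                new_chis, _ = minimize_chis(
                    self.energy_fn(i, parent_id),
                    chis,
                    max_deviation=config.max_deviation,
                    center_chis=parent_chis,
                    max_fun_evals=config.max_fun_evals,
                )
                self.set_placement(i, parent_id, new_chis)
            e_now = self.total()
            if e_prev - e_now < sweep_tol:
                e_prev = min(e_prev, e_now)
                break
            e_prev = e_now
        return e_prev


@dataclass
class MinimisingColony(Colony):
    """A colony whose ants may replace each placement by a subrotamer
    (packing model 1).  With ``max_deviation == 0`` it reduces bit-for-bit
    to the plain discrete colony."""

    context: ContinuousContext = None
    min_config: MinimisationConfig = field(default_factory=MinimisationConfig)
    subrot_sets: dict = field(default_factory=dict)

    def _sset(self, i: int, j: int) -> SubrotamerSet:
        key = (i, j)
        if key not in self.subrot_sets:
            self.subrot_sets[key] = SubrotamerSet(
                j,
                self.context.rotamer_sets[i].rotamers[j].chis,
                max_size=self.min_config.max_subrotamers,
            )
        return self.subrot_sets[key]

    def _construct(self, tau) -> Assignment:
        if self.min_config.max_deviation == 0.0:
            return construct_assignment(
                tau, self.heuristic, self.tables, self.config, self.rng
            )
        from .aco import select_rotamer  # local import to avoid cycle noise

        n = len(self.tables.self_energy)
        choices = np.empty(n, dtype=int)
        chis: list = [None] * n
        self.context.clear()
        for i in self.rng.permutation(n):
            i = int(i)
            j = select_rotamer(i, tau, self.heuristic, self.config, self.rng)
            choices[i] = j
            sset = self._sset(i, j)
            member = extend_subrotamers(
                sset, self.context.energy_fn(i, j), self.rng, self.min_config
            )
            chis[i] = member.chis
            self.context.set_placement(i, j, member.chis)
        return Assignment(choices, self.context.total(), chis)

    def _polish(self, ant: Assignment) -> Assignment:
        if self.min_config.max_deviation == 0.0:
            return super()._polish(ant)
        return ant  # discrete table-based polish would discard subrotamer chis
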