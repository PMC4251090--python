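"""End-to-end packing pipeline: backbone in, side chains out.

The pipeline strips any existing side chains, builds backbone-dependent
rotamer sets, precomputes one interaction table per colony (each colony
owns a different score function), runs the colonies against one shared
pheromone matrix, and rebuilds the structure from the winning assignment.

Because the colonies rank solutions with different energies, the final
structure is chosen by re-scoring every colony's global best under a single
designated reference score function (blind-prediction mode); when a
reference (native) structure is available the closest-to-native best can be
selected instead.
"""

from __future__ import annotations


import numpy as np

from .aco import (
    Assignment,
    Colony,
    ColonyConfig,
    init_pheromone,
    make_colonies,
    run_shop,
    TAU0_DEFAULT,
)
from .energy import (
    ScoreFunction,
    build_interaction_tables,
    builtin_score_functions,
    total_energy,
)
from .rotamers import RotamerLibrary, RotamerSet, build_side_chain, rotamer_sets_for
from .structure import ProteinStructure, strip_side_chains
from .subrot import ContinuousContext, MinimisationConfig, MinimisingColony

__all__ = ["pack", "pack_instance", "pack_with_minimisation"]


def _reference_energy(
    assignment: Assignment,
    ref_context: ContinuousContext,
    ref_tables,
) -> float:
    """Energy of an assignment under the reference score function."""
    if assignment.chis is None:
        return total_energy(assignment.choices, ref_tables)
    ref_context.apply_assignment(assignment)
    return ref_context.total()


def _rebuild(
    backbone: ProteinStructure,
    rotamer_sets: list[RotamerSet],
    assignment: Assignment,
) -> ProteinStructure:
    out = backbone.copy()
    by_index = {r.index: r for r in out.residues}
    for i, (rset, j) in enumerate(zip(rotamer_sets, assignment.choices)):
        chis = (
            assignment.chis[i]
            if assignment.chis is not None
            else rset.rotamers[int(j)].chis
        )
        res = by_index[rset.residue_index]
        rebuilt = build_side_chain(res, rset.residue_type, chis)
        res.atoms = rebuilt.atoms
    return out


def _run(
    backbone: ProteinStructure,
    rotamer_sets: list[RotamerSet],
    score_functions: list[ScoreFunction],
    base_config: ColonyConfig,
    seed: int,
    mode: str,
    model: int | None,
    min_config: MinimisationConfig,
    reference_colony: int,
    tables_per_colony=None,
):
    k = len(score_functions)
    if tables_per_colony is None:
        tables_per_colony = [
            build_interaction_tables(backbone, rotamer_sets, sf)
            for sf in score_functions
        ]
    colonies = make_colonies(tables_per_colony, score_functions, base_config, seed)
    if model in (1, 2):
        colonies = [
            MinimisingColony(
                config=c.config,
                score_function=c.score_function,
                tables=c.tables,
                rng=c.rng,
                context=ContinuousContext(backbone, rotamer_sets, c.score_function),
                min_config=min_config,
            )
            for c in colonies
        ]
    tau = init_pheromone(tables_per_colony[0].sizes, TAU0_DEFAULT)
    bests = run_shop(colonies, tau, mode=mode)

    ref = reference_colony
    if not 0 <= ref < k:
        raise ValueError(f"reference colony {ref} out of range for k={k}")
    ref_ctx = ContinuousContext(backbone, rotamer_sets, score_functions[ref])
    ref_energies = [
        _reference_energy(b, ref_ctx, tables_per_colony[ref]) for b in bests
    ]
    winner = int(np.argmin(ref_energies))
    final = bests[winner].copy()

    if model in (2, 3):
        ref_ctx.apply_assignment(final)
        e_min = ref_ctx.global_minimise(min_config)
        final.chis = [p[1] for p in ref_ctx.placed]
        final.energy = e_min
        ref_energies[winner] = e_min

    report = {
        "seed": int(seed),
        "mode": mode,
        "k": k,
        "model": model,
        "reference_colony": ref,
        "colonies": [
            {
                "id": g,
                "alpha": c.config.alpha,
                "beta": c.config.beta,
                "iterations": c.iteration,
                "best_energy": float(c.s_gb.energy),
                "trace": list(c.trace),
                "choices": [int(j) for j in c.s_gb.choices],
            }
            for g, c in enumerate(colonies)
        ],
        "final": {
            "colony": winner,
            "reference_energy": float(ref_energies[winner]),
            "choices": [int(j) for j in final.choices],
        },
    }
    return final, report


def pack(
    structure: ProteinStructure,
    library: RotamerLibrary,
    k: int = 8,
    seed: int = 0,
    mode: str = "serial",
    base_config: ColonyConfig | None = None,
    score_functions: list[ScoreFunction] | None = None,
    reference_colony: int = 0,
    prob_cutoff: float = 0.98,
) -> tuple[ProteinStructure, dict]:
    """Repack all side chains of a structure on its fixed backbone.

    Returns the packed structure and a machine-readable report (per-colony
    energy traces, iteration counts, chosen rotamers, seed).  ``mode`` is
    ``"serial"`` (round-robin, reproducible) or ``"threaded"``.
    """
    backbone = strip_side_chains(structure)
    rotamer_sets = rotamer_sets_for(backbone, library, prob_cutoff)
    if not rotamer_sets:
        raise ValueError("no packable residues (all Ala/Gly?)")
    sfs = score_functions or builtin_score_functions(k)
    cfg = base_config or ColonyConfig()
    final, report = _run(
        backbone,
        rotamer_sets,
        sfs,
        cfg,
        seed,
        mode,
        model=None,
        min_config=MinimisationConfig(),
        reference_colony=reference_colony,
    )
    packed = _rebuild(backbone, rotamer_sets, final)
    return packed, report


def pack_with_minimisation(
    structure: ProteinStructure,
    library: RotamerLibrary,
    model: int,
    k: int = 8,
    seed: int = 0,
    mode: str = "serial",
    base_config: ColonyConfig | None = None,
    score_functions: list[ScoreFunction] | None = None,
    reference_colony: int = 0,
    min_config: MinimisationConfig | None = None,
    prob_cutoff: float = 0.98,
) -> tuple[ProteinStructure, dict]:
    """Pack with continuous rotamer minimisation (models 1, 2 or 3).

    Model 1 minimises each placement as it is made (subrotamers); model 2
    additionally runs a final all-residue cyclic minimisation; model 3 runs
    the plain discrete search followed by the final minimisation only.
    """
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    backbone = strip_side_chains(structure)
    rotamer_sets = rotamer_sets_for(backbone, library, prob_cutoff)
    if not rotamer_sets:
        raise ValueError("no packable residues (all Ala/Gly?)")
    sfs = score_functions or builtin_score_functions(k)
    cfg = base_config or ColonyConfig()
    final, report = _run(
        backbone,
        rotamer_sets,
        sfs,
        cfg,
        seed,
        mode,
        model=model,
        min_config=min_config or MinimisationConfig(),
        reference_colony=reference_colony,
    )
    packed = _rebuild(backbone, rotamer_sets, final)
    return packed, report


def pack_instance(
    instance,
    base_config: ColonyConfig | None = None,
    k: int = 4,
    seed: int = 0,
    mode: str = "serial",
) -> tuple[ProteinStructure, dict, Assignment]:
    """Pack a :class:`~antpack.fixtures.ToyInstance` with given tables.

    All k colonies share the instance's (possibly synthetic) tables; used
    by the planted-optimum recovery experiments where the tables themselves
    define the problem.  Returns (structure, report, best assignment).
    """
    sfs = builtin_score_functions(k)
    cfg = base_config or ColonyConfig()
    final, report = _run(
        instance.structure,
        instance.rotamer_sets,
        sfs,
        cfg,
        seed,
        mode,
        model=None,
        min_config=MinimisationConfig(),
        reference_colony=0,
        tables_per_colony=[instance.tables] * k,
    )
    packed = _rebuild(instance.structure, instance.rotamer_sets, final)
    return packed, report, final
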