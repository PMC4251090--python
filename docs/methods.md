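# Methods

This note documents the model, the numerical choices, and what the test
fixtures do and do not establish.

## Search model

Packing is cast as discrete assignment: residue i picks rotamer j from its
backbone-dependent set R_i, and the objective is

    E(s) = Σ_i E_self(i, s_i) + Σ_{i<i'} E_pair(i, i', s_i, s_{i'}).

Both tables are precomputed once per score function
(`build_interaction_tables`).  Residue pairs whose Cβ–Cβ distance (Cα for
glycine) exceeds 10 Å are omitted and contribute exactly zero.  Constant
backbone–backbone terms are excluded throughout: only side-chain-dependent
energies can influence the ranking of assignments, so they are ruled out of
the tables.

### Selection, heuristic, update

Selection follows the ant-colony-system rule: with probability q0 the ant
exploits (argmax of τ^α·η^β, ties to the lowest index — sets are ordered by
descending probability, so ties favour the likelier rotamer); otherwise it
explores by a roulette-wheel draw over the same weights (a literal uniform
draw is available via `explore = "uniform"`).

The heuristic η_ij = π/2 − arctan(ΔE_ij) standardises the rotamer's *self*
energy into (0, π).  ΔE is deliberately context-free (backbone interaction
plus the library-statistics term, computed once before the search): this
keeps H a static per-colony matrix, as the single-matrix-per-colony design
implies, and makes η independent of search order.

The pheromone update acts only on the global best's entries:
τ ← (1−ρ)τ + ρ·(π/2 − arctan(E/n)).  Every other entry has Δτ = τ and is an
exact fixed point of the evaporation step.  Two readings of the deposit's
argument are possible from its typeset form; the default normalises the
energy per residue, arctan(E/n), which keeps the deposit scale-free across
protein sizes and inside (0, π).  The alternative reading
(π/2 − arctan(E))/n is available via `eq4_variant = "unnormalized"`.

Local search (best-improvement single-residue sweeps until a full sweep
changes nothing) runs on odd-numbered iterations, counted 1-based, so the
very first iteration is polished.

### Shared-pheromone parallelism

k colonies, each with its own score function and (α, β) exponents, run
against one shared pheromone matrix.  Reads are unsynchronised snapshots;
writes are entry-wise scalar stores (atomic under the runtime's memory
model); no ordering between colonies is guaranteed or required.  A serial
mode interleaves colonies round-robin, one iteration each, and is fully
reproducible; with k = 1 both modes execute the identical code path as a
single colony, which the tests check bit-for-bit.  The point of the
parallelism is hybridising energies, not speed.

Seeding: a master seed spawns one child stream per colony
(`numpy.random.SeedSequence.spawn`); all of a colony's draws (ant visit
permutations, selection draws, subrotamer picks) come from its own stream,
so results are independent of how colonies are interleaved.

The final structure is chosen by re-scoring every colony's global best
under one designated reference score function (default: colony 0).
Selecting by closeness to a native reference is only possible when a native
structure is supplied; blind-prediction mode is the default.

### Default parameters

| parameter | default | notes |
|---|---|---|
| τ0 | π/2 | the deposit at E = 0, so fresh entries are "neutral" |
| ρ | 0.1 | evaporation factor, [0, 1) |
| q0 | 0.9 | exploitation bias |
| n_ants | 16 | per iteration |
| max_iters | 200 | hard cap |
| stagnation_iters | 30 | stop after this many non-improving iterations |
| (α, β) per colony | grid {1,2,3,5}×{1,2,3} | distinct exponent pairs per colony |
| pair cutoff | 10 Å | Cβ–Cβ |
| atom cutoff | 6 Å, switched over 0.5 Å | C¹-smooth switching for minimisation |
| repulsive cap | 10 | soft clash per atom pair |
| library cutoff | 0.98 cumulative probability | at least one rotamer kept |

All are overridable through the TOML config.

## Energies

The contract the search needs is "k distinct, deterministic, finite energy
functions".  The built-in terms are a 12-6 Lennard-Jones pair potential
split into an attractive branch (zero inside the well minimum, the 12-6
value clamped to ≤ 0 outside) and a soft repulsive branch (unit-depth 12-6
excess rising from 0 at r_min, capped at `rep_cap`; r = 0 returns the cap),
with element-based parameters combined Lorentz–Berthelot style, plus a
rotamer-statistics term −ln(p_j/p_max) from library frequencies.  Eight
presets vary the three weights.  Intra-residue atom pairs separated by ≤ 3
bonds are excluded.  Splitting the two LJ branches lets presets soften
clashes independently of packing reward, the same design choice soft-core
packing potentials make.

Note one deliberate non-smoothness: the attractive branch is defined as
exactly 0 for r < r_min, so the total pair potential has a step of ε·w_atr
at contact distance.  In practice the capped repulsive branch dominates
that region and the finite-difference minimiser is unaffected at the
tolerances used.

## Geometry

Side chains are built by sequential internal-coordinate (NeRF)
construction from per-type Z-matrix templates with ideal bond lengths and
angles derived from standard energy-minimised amino-acid component
geometry; each χ drives one proper dihedral, branch atoms ride at fixed
offsets (e.g. Leu CD2 at χ2 + 120°), and ring atoms use frozen torsions.
Build→measure round-trips recover χ to < 1e-12° in practice (the tests
require 1e-6°).  Hydrogens are never read or generated.  The dihedral sign
convention is IUPAC (positive = clockwise looking down the bond); note that
a torsion angle is invariant under reversing the atom order and changes
sign only under mirror reflection.

Chain termini with undefined φ or ψ fall back to the (−60, −40) helical
library bin; bin lookup is nearest-centre on the (φ, ψ) torus.

## Continuous minimisation (subrotamers)

`minimize_chis` runs L-BFGS-B on the residue's energy as a function of its
χ vector, others fixed, with finite-difference gradients (the switched
cutoffs make the energy smooth) and box bounds of ±15° (default) around the
*parent* rotamer, which keeps every subrotamer attributable to its parent
for χ-accuracy bookkeeping.  The subrotamer set A_ij starts as {r_j}; an
extension picks a member uniformly at random (the pick distribution is
otherwise unspecified in the literature the design follows), minimises it
in context, and prepends it only on a strict energy drop (> 1e-9); the
primary rotamer is always retained as the last member and the set is capped
at 8 members (oldest non-primary evicted).  Subrotamers share their
parent's pheromone entry.

Model 1 applies this at every ant placement, in the context of the residues
that ant has already placed; model 2 adds a final cyclic all-residue
minimisation of the winning assignment (≤ 10 sweeps or < 1e-6
improvement); model 3 is the plain discrete search plus the final
minimisation.  With `max_deviation = 0` model 1 short-circuits to the plain
discrete colony, bit-for-bit (no extra random draws).  Minimising colonies
skip the discrete table-based local-search polish: it would silently
discard the continuous chi values it cannot represent.

Model 2 ≤ model 1 in final energy by construction (an extra descent step).
Model 1 versus the plain search is not an inequality that holds for
arbitrary diverging stochastic trajectories; it does hold whenever both
searches reach the same discrete optimum, since accepted minimisation steps
only lower the energy from that shared floor — the comparison fixtures are
chosen small enough that the discrete search converges.

## Synthetic fixtures and what they show

`make_random_instance` draws self energies U[0, 5] and pair energies
U[−1, 1] (present with a configurable density) over real ideal-geometry
backbones; `make_planted_instance` additionally implants a designated
assignment as the unique global optimum by uniformly lowering its self
energies until enumeration verifies the requested margin, and materialises
the planted rotamers as a native structure so pack→evaluate closes the
loop.  The exhaustive-enumeration oracle (guarded at 10⁶ states, ties to
the lexicographically smallest vector) is the ground truth for every
search claim.

These fixtures exercise the combinatorial search, the bookkeeping and the
evaluation logic exactly, but their energy surfaces are far smoother and
smaller than a real protein's, and the bundled toy rotamer library (3
rotamers per type on a coarse 120° φ/ψ grid, mild deterministic backbone
drift) is synthetic.  Passing them demonstrates correctness of the
machinery, not prediction accuracy on real structures; accuracy on real
proteins additionally depends on the rotamer library and energy functions
supplied.

Problem sizes used by the acceptance script — 100 random instances (n = 6
residues, m = 4 rotamers), 20 planted instances (n = 8, m = 4, margin 1),
100 paired seeds for the shared-vs-isolated comparison with 4 reduced-budget
colonies, 25 χ round-trip samples per residue type — are chosen so the whole
script completes in well under a minute while keeping binomial noise on the
reported rates a few percent.

## Known limitations

* Single chain, heavy atoms only; no ligands, nucleic acids or mmCIF.
* The energy presets are simple LJ + statistics stand-ins; solvation,
  hydrogen bonding, electrostatics and disulfide terms are out of scope.
* Proline is packed like any other residue; its ring-closure strain is not
  scored.
* The shared-vs-isolated comparison is a reported Monte-Carlo metric, not a
  theorem; on small instances both arms typically saturate.
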