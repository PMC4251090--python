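"""Ant-colony search for side-chain packing, and the shared-pheromone
parallel runner (SHOP: several colonies, each guided by its own energy
function, reading and reinforcing one common pheromone matrix).

One colony iteration:

1. every ant assembles a full assignment, choosing a rotamer per residue by
   the pseudo-random-proportional selection rule
   (``argmax_j tau_ij^alpha * eta_ij^beta`` with probability ``q0``,
   otherwise a roulette-wheel draw over the same weights);
2. on odd-numbered iterations each ant's assignment is polished by
   best-improvement local search;
3. the iteration best updates the colony's global best ``s_gb`` when lower;
4. the pheromone entries on ``s_gb``'s choices relax toward the deposit
   ``pi/2 - arctan(E(s_gb)/n)``; all other entries are exact fixed points of
   the update.

The heuristic desirability is the standardised single-rotamer energy
``eta_ij = pi/2 - arctan(dE_ij)``, which maps any finite energy into
(0, pi) with lower energies more desirable.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field, replace

import numpy as np

from .energy import InteractionTables, ScoreFunction, total_energy

__all__ = [
    "PheromoneMatrix",
    "HeuristicMatrix",
    "ColonyConfig",
    "Assignment",
    "Colony",
    "init_pheromone",
    "compute_heuristic",
    "select_rotamer",
    "construct_assignment",
    "local_search",
    "update_pheromone",
    "run_colony",
    "run_shop",
]

TAU0_DEFAULT = float(np.pi / 2)  # the deposit at E = 0


class PheromoneMatrix:
    """Ragged matrix tau[i][j] > 0 over (residue, rotamer) pairs.

    A single instance may be shared by several concurrently running
    colonies; writes go entry-by-entry (atomic scalar stores), reads are
    unsynchronised snapshots.
    """

    def __init__(self, tau: list[np.ndarray], tau0: float):
        self.tau = tau
        self.tau0 = tau0

    @classmethod
    def uniform(cls, sizes, tau0: float) -> "PheromoneMatrix":
        if tau0 <= 0:
            raise ValueError("tau0 must be positive")
        return cls([np.full(m, float(tau0)) for m in sizes], float(tau0))

    @property
    def sizes(self):
        return [len(t) for t in self.tau]

    def copy(self) -> "PheromoneMatrix":
        return PheromoneMatrix([t.copy() for t in self.tau], self.tau0)


class HeuristicMatrix:
    """Static per-colony desirability eta[i][j] in the open interval (0, pi)."""

    def __init__(self, eta: list[np.ndarray]):
        self.eta = eta


@dataclass(frozen=True)
class ColonyConfig:
    """Control parameters of one colony."""

    alpha: float = 1.0
    beta: float = 2.0
    q0: float = 0.9
    rho: float = 0.1
    n_ants: int = 16
    max_iters: int = 200
    stagnation_iters: int = 30
    seed: int = 0
    explore: str = "proportional"  # or "uniform"
    eq4_variant: str = "normalized"  # or "unnormalized"

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must lie in [0, 1]")
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if self.explore not in ("proportional", "uniform"):
            raise ValueError("explore must be 'proportional' or 'uniform'")
        if self.eq4_variant not in ("normalized", "unnormalized"):
            raise ValueError("eq4_variant must be 'normalized' or 'unnormalized'")


@dataclass
class Assignment:
    """One rotamer index per packable residue plus its energy.

    ``chis`` optionally carries continuous (subrotamer) chi tuples per
    residue when a placement deviates from the library rotamer.
    """

    choices: np.ndarray
    energy: float
    chis: list | None = None

    def copy(self) -> "Assignment":
        return Assignment(
            self.choices.copy(),
            self.energy,
            None if self.chis is None else list(self.chis),
        )


def init_pheromone(sizes, tau0: float = TAU0_DEFAULT) -> PheromoneMatrix:
    """Uniform pheromone matrix with every entry equal to ``tau0`` (> 0)."""
    return PheromoneMatrix.uniform(sizes, tau0)


def compute_heuristic(tables: InteractionTables) -> HeuristicMatrix:
    """Standardise single-rotamer self energies into desirabilities.

    ``eta_ij = pi/2 - arctan(dE_ij)`` where dE is the energy induced by
    residue i picking rotamer j against the fixed backbone context; the
    result always lies in (0, pi) and decreases with increasing energy.
    """
    return HeuristicMatrix([np.pi / 2 - np.arctan(se) for se in tables.self_energy])


def _weights(tau_i, eta_i, config: ColonyConfig):
    return tau_i**config.alpha * eta_i**config.beta


def select_rotamer(
    i: int,
    tau: PheromoneMatrix,
    eta: HeuristicMatrix,
    config: ColonyConfig,
    rng: np.random.Generator,
) -> int:
    """Pseudo-random-proportional rotamer choice for residue ``i``.

    Draws q ~ U[0,1); if q < q0, exploit: the j maximising
    ``tau_ij^alpha * eta_ij^beta`` (ties broken toward the lowest index,
    i.e. the more probable rotamer).  Otherwise explore: a roulette-wheel
    draw proportional to the same weights (or uniform when
    ``config.explore == "uniform"``).
    """
    tau_i = tau.tau[i]
    if len(tau_i) == 0:
        raise ValueError(f"residue {i}: empty candidate set")
    q = rng.random()
    w = _weights(tau_i, eta.eta[i], config)
    if q < config.q0:
        return int(np.argmax(w))
    if config.explore == "uniform":
        return int(rng.integers(len(w)))
    cdf = np.cumsum(w)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


def construct_assignment(
    tau: PheromoneMatrix,
    eta: HeuristicMatrix,
    tables: InteractionTables,
    config: ColonyConfig,
    rng: np.random.Generator,
) -> Assignment:
    """One ant builds a complete assignment.

    Residues are visited in a random permutation (the selection rule itself
    is context-free, but the visit order fixes the rng draw order and is
    what downstream per-placement refinement hooks see).
    """
    n = len(tables.self_energy)
    choices = np.empty(n, dtype=int)
    for i in rng.permutation(n):
        choices[i] = select_rotamer(int(i), tau, eta, config, rng)
    return Assignment(choices, total_energy(choices, tables))


def local_search(assignment: Assignment, tables: InteractionTables) -> Assignment:
    """Best-improvement sweeps: per residue, switch to the rotamer that
    minimises the total energy with all other residues held fixed; repeat
    until a full sweep changes nothing.  Never increases the energy."""
    choices = assignment.choices.copy()
    n = len(tables.self_energy)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            cand = tables.self_energy[i].copy()
            for b, mat in tables.neighbors[i]:
                cand = cand + mat[:, choices[b]]
            j = int(np.argmin(cand))
            if j != choices[i] and cand[j] < cand[choices[i]] - 1e-12:
                choices[i] = j
                improved = True
    return Assignment(choices, total_energy(choices, tables))


def _deposit(energy: float, n: int, variant: str) -> float:
    if variant == "unnormalized":
        return float((np.pi / 2 - np.arctan(energy)) / n)
    return float(np.pi / 2 - np.arctan(energy / n))


def update_pheromone(
    tau: PheromoneMatrix,
    s_gb: Assignment,
    n: int,
    rho: float,
    eq4_variant: str = "normalized",
) -> PheromoneMatrix:
    """Evaporate-and-deposit update on the global best's entries.

    ``tau_ij <- (1 - rho) tau_ij + rho * dtau_ij`` where the deposit on the
    entries chosen by ``s_gb`` is ``pi/2 - arctan(E(s_gb)/n)`` and every
    other entry's dtau equals its own tau, making it an exact fixed point.
    The matrix is updated in place (entry-wise) and returned.
    """
    dep = _deposit(s_gb.energy, n, eq4_variant)
    for i, j in enumerate(s_gb.choices):
        tau.tau[i][j] = (1.0 - rho) * tau.tau[i][j] + rho * dep
    return tau


@dataclass
class Colony:
    """State of one ant colony: its energy tables, heuristic, rng and best."""

    config: ColonyConfig
    score_function: ScoreFunction
    tables: InteractionTables
    heuristic: HeuristicMatrix = None
    rng: np.random.Generator = None
    s_gb: Assignment = None
    iteration: int = 0
    stagnation: int = 0
    done: bool = False
    trace: list = field(default_factory=list)

    def __post_init__(self):
        if self.heuristic is None:
            self.heuristic = compute_heuristic(self.tables)
        if self.rng is None:
            self.rng = np.random.default_rng(
                np.random.SeedSequence(self.config.seed)
            )

    # hook point for per-placement refinement (continuous minimisation)
    def _construct(self, tau: PheromoneMatrix) -> Assignment:
        return construct_assignment(tau, self.heuristic, self.tables, self.config, self.rng)

    def _polish(self, ant: Assignment) -> Assignment:
        return local_search(ant, self.tables)

    def step(self, tau: PheromoneMatrix) -> None:
        """One iteration (1-based counting; local search on odd iterations)."""
        if self.done:
            return
        self.iteration += 1
        ants = [self._construct(tau) for _ in range(self.config.n_ants)]
        if self.iteration % 2 == 1:
            ants = [self._polish(a) for a in ants]
        s_ib = min(ants, key=lambda a: a.energy)
        if self.s_gb is None or s_ib.energy < self.s_gb.energy:
            self.s_gb = s_ib.copy()
            self.stagnation = 0
        else:
            self.stagnation += 1
        update_pheromone(
            tau,
            self.s_gb,
            n=len(self.tables.self_energy),
            rho=self.config.rho,
            eq4_variant=self.config.eq4_variant,
        )
        self.trace.append(float(self.s_gb.energy))
        if (
            self.iteration >= self.config.max_iters
            or self.stagnation >= self.config.stagnation_iters
        ):
            self.done = True


def run_colony(colony: Colony, tau: PheromoneMatrix) -> Assignment:
    """Run a single colony to termination; returns its global best."""
    while not colony.done:
        colony.step(tau)
    return colony.s_gb


def run_shop(
    colonies: list[Colony],
    tau: PheromoneMatrix,
    mode: str = "serial",
) -> list[Assignment]:
    """Run k colonies against one shared pheromone matrix.

    ``mode="serial"`` interleaves colonies round-robin, one iteration each,
    which is fully reproducible; ``mode="threaded"`` runs one thread per
    colony (entry-wise atomic pheromone writes, snapshot reads, no ordering
    guarantees).  With k = 1 both modes are bit-identical to
    :func:`run_colony` under the same seed.  Returns each colony's s_gb.
    """
    if mode not in ("serial", "threaded"):
        raise ValueError("mode must be 'serial' or 'threaded'")
    if mode == "threaded":
        threads = [
            threading.Thread(target=run_colony, args=(c, tau)) for c in colonies
        ]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
    else:
        while not all(c.done for c in colonies):
            for c in colonies:
                c.step(tau)
    return [c.s_gb for c in colonies]


def make_colonies(
    tables_per_colony: list[InteractionTables],
    score_functions: list[ScoreFunction],
    base_config: ColonyConfig,
    master_seed: int,
    alphas_betas: list[tuple[float, float]] | None = None,
) -> list[Colony]:
    """Construct k colonies with per-colony seeds spawned from a master seed.

    ``alphas_betas`` overrides (alpha, beta) per colony; by default colonies
    walk a small grid of exponents so that pheromone and heuristic influence
    are weighted differently in each colony.
    """
    if len(tables_per_colony) != len(score_functions):
        raise ValueError("need one score function per colony")
    k = len(score_functions)
    if alphas_betas is None:
        grid = [(1, 1), (2, 1), (3, 2), (5, 1), (1, 2), (2, 3), (3, 1), (5, 2)]
        alphas_betas = [grid[g % len(grid)] for g in range(k)]
    seeds = np.random.SeedSequence(master_seed).spawn(k)
    colonies = []
    for g in range(k):
        cfg = replace(
            base_config,
            alpha=float(alphas_betas[g][0]),
            beta=float(alphas_betas[g][1]),
        )
        colonies.append(
            Colony(
                config=cfg,
                score_function=score_functions[g],
                tables=tables_per_colony[g],
                rng=np.random.default_rng(seeds[g]),
            )
        )
    return colonies
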