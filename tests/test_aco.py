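import numpy as np
import pytest

from antpack import (
    Assignment,
    Colony,
    ColonyConfig,
    builtin_score_functions,
    compute_heuristic,
    construct_assignment,
    init_pheromone,
    local_search,
    run_colony,
    select_rotamer,
    total_energy,
    update_pheromone,
)
from antpack.aco import HeuristicMatrix, PheromoneMatrix
from antpack.energy import InteractionTables
from antpack.fixtures import enumerate_optimum, make_random_instance


def _tables(self_energies, pairs=None):
    return InteractionTables(
        self_energy=[np.asarray(s, dtype=float) for s in self_energies],
        pair_energy={k: np.asarray(v, dtype=float) for k, v in (pairs or {}).items()},
    )


class TestInitPheromone:
    def test_uniform_fill(self):
        tau = init_pheromone([3, 2], tau0=1.0)
        assert [len(t) for t in tau.tau] == [3, 2]
        assert all(np.all(t == 1.0) for t in tau.tau)

    def test_nonpositive_tau0_rejected(self):
        with pytest.raises(ValueError):
            init_pheromone([3, 2], tau0=0.0)


class TestComputeHeuristic:
    def test_standardisation_reference_values(self):
        eta = compute_heuristic(_tables([[0.0, 1.0, -1.0]]))
        np.testing.assert_allclose(
            eta.eta[0], [np.pi / 2, np.pi / 4, 3 * np.pi / 4], atol=1e-12
        )

    def test_range_and_monotonicity(self, rng):
        es = rng.normal(scale=50, size=200)
        eta = compute_heuristic(_tables([es]))
        vals = eta.eta[0]
        assert np.all((vals > 0) & (vals < np.pi))
        order = np.argsort(es)
        assert np.all(np.diff(vals[order]) <= 0)


class TestSelectRotamer:
    def _setup(self, tau_vals, eta_vals):
        tau = PheromoneMatrix([np.asarray(tau_vals, dtype=float)], 1.0)
        eta = HeuristicMatrix([np.asarray(eta_vals, dtype=float)])
        return tau, eta

    def test_exploitation_argmax(self, rng):
        tau, eta = self._setup([1.0, 2.0], [1.0, 1.0])
        cfg = ColonyConfig(alpha=1, beta=1, q0=1.0)
        assert select_rotamer(0, tau, eta, cfg, rng) == 1

    def test_tie_broken_toward_lowest_index(self, rng):
        tau, eta = self._setup([2.0, 2.0], [3.0, 1.0])
        cfg = ColonyConfig(alpha=1, beta=0, q0=1.0)
        assert select_rotamer(0, tau, eta, cfg, rng) == 0

    def test_exploration_sampling_frequency(self):
        # weights (1, 3): P(j=1) = 0.75; binomial 3-sigma check at N = 1e5
        tau, eta = self._setup([1.0, 3.0], [1.0, 1.0])
        cfg = ColonyConfig(alpha=1, beta=1, q0=0.0)
        rng = np.random.default_rng(42)
        n = 100_000
        hits = sum(select_rotamer(0, tau, eta, cfg, rng) == 1 for _ in range(n))
        p = 0.75
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_uniform_exploration_mode(self):
        tau, eta = self._setup([1.0, 1000.0], [1.0, 1.0])
        cfg = ColonyConfig(alpha=1, beta=1, q0=0.0, explore="uniform")
        rng = np.random.default_rng(7)
        n = 20_000
        hits = sum(select_rotamer(0, tau, eta, cfg, rng) == 1 for _ in range(n))
        sigma = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 4 * sigma

    def test_empty_candidate_set_rejected(self, rng):
        tau = PheromoneMatrix([np.array([])], 1.0)
        eta = HeuristicMatrix([np.array([])])
        with pytest.raises(ValueError):
            select_rotamer(0, tau, eta, ColonyConfig(), rng)


class TestConstructAssignment:
    def test_singleton_sets_deterministic(self, rng):
        tables = _tables([[2.0], [1.0], [0.5]])
        tau = init_pheromone(tables.sizes)
        eta = compute_heuristic(tables)
        a = construct_assignment(tau, eta, tables, ColonyConfig(), rng)
        assert list(a.choices) == [0, 0, 0]
        assert a.energy == pytest.approx(3.5)

    def test_energy_consistent_with_tables(self, rng):
        inst = make_random_instance(5, 3, 0.6, seed=11)
        tau = init_pheromone(inst.tables.sizes)
        eta = compute_heuristic(inst.tables)
        for _ in range(10):
            a = construct_assignment(tau, eta, inst.tables, ColonyConfig(), rng)
            assert a.energy == pytest.approx(total_energy(a.choices, inst.tables))

    def test_greedy_when_fully_exploiting_uniform_tau(self, rng):
        inst = make_random_instance(6, 4, 0.5, seed=2)
        tau = init_pheromone(inst.tables.sizes)
        eta = compute_heuristic(inst.tables)
        cfg = ColonyConfig(q0=1.0)
        a = construct_assignment(tau, eta, inst.tables, cfg, rng)
        # independent greedy oracle: argmax eta per residue (tau uniform)
        greedy = [int(np.argmax(e)) for e in eta.eta]
        assert list(a.choices) == greedy


class TestLocalSearch:
    def test_fixed_point_at_local_optimum(self):
        tables = _tables([[0.0, 5.0], [0.0, 5.0]])
        a = Assignment(np.array([0, 0]), total_energy([0, 0], tables))
        out = local_search(a, tables)
        assert list(out.choices) == [0, 0]

    def test_single_residue_finds_global_optimum(self):
        tables = _tables([[3.2, 1.1, 2.0]])
        a = Assignment(np.array([0]), 3.2)
        out = local_search(a, tables)
        assert list(out.choices) == [1]
        assert out.energy == pytest.approx(1.1)

    def test_never_increases_energy(self, rng):
        for seed in range(20):
            inst = make_random_instance(5, 3, 0.7, seed=seed)
            choices = np.array([rng.integers(3) for _ in range(5)])
            a = Assignment(choices, total_energy(choices, inst.tables))
            out = local_search(a, inst.tables)
            assert out.energy <= a.energy + 1e-12


class TestUpdatePheromone:
    def test_zero_rho_leaves_matrix_unchanged(self):
        tau = init_pheromone([2, 2], tau0=1.3)
        before = [t.copy() for t in tau.tau]
        update_pheromone(tau, Assignment(np.array([0, 1]), 5.0), n=2, rho=0.0)
        for b, t in zip(before, tau.tau):
            np.testing.assert_array_equal(b, t)

    def test_non_elite_entries_are_fixed_points(self):
        tau = init_pheromone([3, 3], tau0=0.8)
        update_pheromone(tau, Assignment(np.array([1, 2]), -4.0), n=2, rho=0.5)
        assert tau.tau[0][0] == 0.8 and tau.tau[0][2] == 0.8
        assert tau.tau[1][0] == 0.8 and tau.tau[1][1] == 0.8
        assert tau.tau[0][1] != 0.8 and tau.tau[1][2] != 0.8

    def test_reference_arithmetic(self):
        # tau = 1, rho = 0.5, E = 0: tau' = 0.5 + 0.5 * pi/2 = 1.285398...
        tau = init_pheromone([1], tau0=1.0)
        update_pheromone(tau, Assignment(np.array([0]), 0.0), n=1, rho=0.5)
        assert tau.tau[0][0] == pytest.approx(0.5 + 0.25 * np.pi, abs=1e-12)
        assert tau.tau[0][0] == pytest.approx(1.285398, abs=1e-6)

    def test_deposit_normalised_per_residue(self):
        # with the normalised variant, scaling E and n together is invariant
        t1 = init_pheromone([1], tau0=1.0)
        update_pheromone(t1, Assignment(np.array([0]), 10.0), n=5, rho=0.3)
        t2 = init_pheromone([1], tau0=1.0)
        update_pheromone(t2, Assignment(np.array([0]), 20.0), n=10, rho=0.3)
        assert t1.tau[0][0] == pytest.approx(t2.tau[0][0])


class TestRunColony:
    def _colony(self, tables, **kw):
        cfg = ColonyConfig(**kw)
        return Colony(
            config=cfg,
            score_function=builtin_score_functions(1)[0],
            tables=tables,
        )

    def test_singleton_sets_terminate_by_stagnation(self):
        tables = _tables([[1.0], [2.0]])
        col = self._colony(tables, stagnation_iters=5, max_iters=100, seed=1)
        best = run_colony(col, init_pheromone(tables.sizes))
        assert list(best.choices) == [0, 0]
        assert col.iteration == 6  # first improves, then 5 stagnant

    def test_best_energy_trace_monotone(self):
        inst = make_random_instance(6, 4, 0.5, seed=5)
        col = self._colony(inst.tables, seed=5)
        run_colony(col, init_pheromone(inst.tables.sizes))
        assert all(b <= a + 1e-12 for a, b in zip(col.trace, col.trace[1:]))

    def test_pheromone_stays_in_bounds(self):
        inst = make_random_instance(5, 3, 0.5, seed=9)
        col = self._colony(inst.tables, seed=9)
        tau = init_pheromone(inst.tables.sizes)
        run_colony(col, tau)
        hi = max(tau.tau0, np.pi)
        for t in tau.tau:
            assert np.all((t > 0) & (t <= hi + 1e-12))

    def test_reaches_enumerated_optimum_on_small_instances(self):
        hits = 0
        for seed in range(10):
            inst = make_random_instance(5, 3, 0.5, seed=seed)
            opt = enumerate_optimum(inst.tables)
            col = self._colony(inst.tables, seed=seed)
            best = run_colony(col, init_pheromone(inst.tables.sizes))
            hits += abs(best.energy - opt.energy) < 1e-9
        assert hits >= 9


class TestColonyConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"rho": 1.0},
            {"rho": -0.1},
            {"q0": 1.5},
            {"n_ants": 0},
            {"explore": "sometimes"},
            {"eq4_variant": "both"},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ColonyConfig(**kw)
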