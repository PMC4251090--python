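import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from antpack import (
    ScoreFunction,
    build_interaction_tables,
    builtin_score_functions,
    lj_attractive,
    lj_repulsive,
    rotamer_statistics_term,
    total_energy,
)
from antpack.energy import (
    InteractionTables,
    _switch,
    bond_separation,
    pair_lj_energy,
    PAIR_CUTOFF,
)
from antpack.fixtures import make_backbone
from antpack.rotamers import Rotamer, RotamerSet, build_side_chain, rotamer_sets_for
from antpack.structure import strip_side_chains


class TestLennardJones:
    def test_attractive_well_minimum(self):
        assert lj_attractive(3.9, 3.9, 0.2) == pytest.approx(-0.2)

    def test_attractive_vanishes_at_long_range(self):
        assert abs(lj_attractive(39.0, 3.9, 0.2)) < 1e-5 * 0.2

    def test_attractive_clamped_inside_well(self):
        assert lj_attractive(1.95, 3.9, 0.2) == 0.0

    def test_attractive_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            lj_attractive(0.0, 3.9, 0.2)

    def test_repulsive_boundary_and_origin(self):
        assert lj_repulsive(3.9, 3.9, 10.0) == pytest.approx(0.0)
        assert lj_repulsive(0.0, 3.9, 10.0) == 10.0

    def test_repulsive_monotone_nonincreasing(self):
        r = np.linspace(0.0, 6.0, 100)
        v = np.array([lj_repulsive(x, 3.9, 10.0) for x in r])
        assert np.all(np.diff(v) <= 1e-12)
        assert np.all((v >= 0) & (v <= 10.0))


class TestRotamerStatistics:
    def _set(self, probs):
        rots = [Rotamer(chis=(-60.0,), probability=p, id=j) for j, p in enumerate(probs)]
        return RotamerSet(residue_index=1, residue_type="SER", rotamers=rots)

    def test_most_probable_is_zero(self):
        s = self._set([0.5, 0.3])
        assert rotamer_statistics_term(s.rotamers[0], s) == 0.0

    @pytest.mark.parametrize("factor,expected", [(np.e, 1.0), (np.e**2, 2.0)])
    def test_log_ratio(self, factor, expected):
        s = self._set([0.6, 0.6 / factor])
        assert rotamer_statistics_term(s.rotamers[1], s) == pytest.approx(expected)


class TestScoreFunctions:
    def test_eight_distinct_presets(self):
        sfs = builtin_score_functions(8)
        weight_maps = [tuple(sorted(sf.weights.items())) for sf in sfs]
        assert len(set(weight_maps)) == 8

    def test_single_preset(self):
        assert len(builtin_score_functions(1)) == 1

    @pytest.mark.parametrize("k", [0, 9])
    def test_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            builtin_score_functions(k)

    def test_all_presets_finite_on_fixture(self, packing_setup):
        backbone, sets, _, _ = packing_setup
        for sf in builtin_score_functions(8):
            tables = build_interaction_tables(backbone, sets, sf)
            choices = [0] * len(sets)
            assert np.isfinite(total_energy(choices, tables))

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            ScoreFunction(id=0, weights={"lj_atr": 0.0})


class TestInteractionTables:
    def test_distant_residues_have_no_pair_entry(self, toy_library):
        bb = make_backbone(2, "helix", sequence="SS")
        # move the second residue 50 A away
        for a in bb.residues[1].atoms:
            a.position = a.position + np.array([50.0, 0.0, 0.0])
        sets = rotamer_sets_for(bb, toy_library)
        tables = build_interaction_tables(bb, sets, builtin_score_functions(1)[0])
        assert tables.pair_energy == {}
        assert tables.pair(0, 1, 0, 0) == 0.0

    def test_pair_access_symmetric(self, packing_setup):
        _, _, _, tables = packing_setup
        for (a, b), mat in tables.pair_energy.items():
            for ja in range(mat.shape[0]):
                for jb in range(mat.shape[1]):
                    assert tables.pair(a, b, ja, jb) == tables.pair(b, a, jb, ja)

    def test_single_residue_structure(self, toy_library):
        bb = make_backbone(1, "helix", sequence="S")
        sets = rotamer_sets_for(bb, toy_library)
        tables = build_interaction_tables(bb, sets, builtin_score_functions(1)[0])
        assert tables.pair_energy == {}
        assert len(tables.self_energy) == 1
        assert len(tables.self_energy[0]) == len(sets[0])


class TestTotalEnergy:
    def test_empty_problem(self):
        tables = InteractionTables(self_energy=[], pair_energy={})
        assert total_energy([], tables) == 0.0

    def test_single_residue_selects_self_energy(self):
        tables = InteractionTables(
            self_energy=[np.array([3.2, 1.1, 2.0])], pair_energy={}
        )
        assert total_energy([1], tables) == pytest.approx(1.1)

    def test_incomplete_assignment_rejected(self):
        tables = InteractionTables(
            self_energy=[np.array([1.0]), np.array([1.0])], pair_energy={}
        )
        with pytest.raises(ValueError):
            total_energy([0], tables)

    def test_matches_direct_term_evaluation(self, packing_setup, rng):
        """Tables reproduce an independent term-by-term evaluation of the
        fully built structure (20 random assignments, 1e-9)."""
        backbone, sets, sf, tables = packing_setup
        from antpack.energy import (
            _anchor_position,
            _backbone_frame_atoms,
            _side_chain_atoms,
        )

        by_index = {r.index: (pos, r) for pos, r in enumerate(backbone.residues)}
        for _ in range(20):
            choices = [int(rng.integers(len(s))) for s in sets]
            placed = [
                build_side_chain(
                    by_index[s.residue_index][1], s.residue_type, s.rotamers[j].chis
                )
                for s, j in zip(sets, choices)
            ]
            # direct evaluation: every side chain vs every backbone frame and
            # every other side chain within the anchor cutoff, plus statistics
            direct = 0.0
            for i, (s, j, p) in enumerate(zip(sets, choices, placed)):
                direct += sf.weights["rot_stat"] * rotamer_statistics_term(
                    s.rotamers[j], s
                )
                sc_c, sc_e, sc_n = _side_chain_atoms(p)
                for res in backbone.residues:
                    bb_c, bb_e, bb_n = _backbone_frame_atoms(res)
                    if res.index == s.residue_index:
                        for c1, e1, n1 in zip(sc_c, sc_e, sc_n):
                            for c2, e2, n2 in zip(bb_c, bb_e, bb_n):
                                if bond_separation(p.type, n1, n2) > 3:
                                    direct += pair_lj_energy(
                                        [c1], [e1], [c2], [e2], sf.weights
                                    )
                    else:
                        direct += pair_lj_energy(sc_c, sc_e, bb_c, bb_e, sf.weights)
                for i2 in range(i + 1, len(sets)):
                    a1 = _anchor_position(by_index[sets[i].residue_index][1])
                    a2 = _anchor_position(by_index[sets[i2].residue_index][1])
                    if np.linalg.norm(a1 - a2) <= PAIR_CUTOFF:
                        o_c, o_e, _ = _side_chain_atoms(placed[i2])
                        direct += pair_lj_energy(sc_c, sc_e, o_c, o_e, sf.weights)
            assert total_energy(choices, tables) == pytest.approx(direct, abs=1e-9)

    def test_invariant_under_rigid_transform(self, packing_setup, rng):
        backbone, sets, sf, tables = packing_setup
        moved = backbone.copy()
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.normal(size=3) * 20
        for res in moved.residues:
            for a in res.atoms:
                a.position = rot @ a.position + shift
        moved.compute_backbone_dihedrals()
        tables2 = build_interaction_tables(moved, sets, sf)
        choices = [0] * len(sets)
        assert total_energy(choices, tables2) == pytest.approx(
            total_energy(choices, tables), abs=1e-6
        )

    def test_linear_in_weights(self, packing_setup, rng):
        backbone, sets, sf, tables = packing_setup
        doubled = ScoreFunction(
            id=99, weights={k: 2 * v for k, v in sf.weights.items()}
        )
        tables2 = build_interaction_tables(backbone, sets, doubled)
        for _ in range(5):
            choices = [int(rng.integers(len(s))) for s in sets]
            assert total_energy(choices, tables2) == pytest.approx(
                2.0 * total_energy(choices, tables), abs=1e-9
            )


def test_switch_function_smooth_bounds():
    r = np.linspace(0, 8, 200)
    v = _switch(r)
    assert np.all((v >= 0) & (v <= 1))
    assert _switch(5.5) == 1.0
    assert _switch(6.0) == 0.0
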