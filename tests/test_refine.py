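import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pcalign as pc
from pcalign.errors import DegenerateGeometryError
from pcalign.geom_hash import Candidate
from pcalign.refine import equivalence_score, kabsch_superpose, optimal_matching
from conftest import toy_interface


class TestEquivalenceScore:
    @pytest.mark.parametrize("d,same,expected", [
        (0.0, 1, 1.0),          # maximum: superposed, identical class
        (0.0, 0, 0.8),          # 1/1.25, the chemical-mismatch ceiling
        (8.0, 1, 0.2),          # 1/(1+64/16): the inclusion-threshold distance
        (4.0, 1, 0.5),
    ])
    def test_closed_form_values(self, d, same, expected):
        assert equivalence_score(d, same) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 20, 200)
        s = equivalence_score(d, 1)
        assert np.all(np.diff(s) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            equivalence_score(-0.1, 1)


class TestOptimalMatching:
    def test_identity_geometry_gives_identity_matching(self):
        a = [[0, 0, 0], [5, 0, 0], [0, 5, 1]]
        iface = toy_interface(a, [[0, 0, 6], [5, 0, 6], [0, 5, 7]])
        pairs = optimal_matching(iface, iface, pc.RigidTransform.identity())
        assert [(p.idx1, p.idx2) for p in pairs] == [(i, i) for i in range(6)]
        assert all(p.d == pytest.approx(0.0) and p.eq_score == pytest.approx(1.0)
                   for p in pairs)

    def test_beats_greedy_assignment(self):
        # fragment A: residue 0 is close to both B'-side residues, so greedy
        # matching (best pair first) picks (0,0) and strands residue 1 far away;
        # the optimal assignment crosses to (0,1),(1,0)
        i1 = toy_interface([[0, 0, 0], [2.0, 0, 0]], [[0, 0, 5], [5, 0, 5], [0, 5, 5]])
        i2 = toy_interface([[0.5, 0, 0], [0.0, 0, 0]], [[0, 0, 5], [5, 0, 5], [0, 5, 5]])
        pairs = optimal_matching(i1, i2, pc.RigidTransform.identity())
        a_pairs = [(p.idx1, p.idx2) for p in pairs if p.idx1 < 2]
        assert a_pairs == [(0, 1), (1, 0)]

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_permutation_optimum(self, seed):
        """Hungarian total equals the exhaustive optimum on small instances."""
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
        aas = list("KRNEDQFWAC")
        i1 = toy_interface(rng.uniform(0, 15, (na, 3)), rng.uniform(0, 15, (3, 3)),
                           aas_a=[aas[i] for i in rng.integers(0, 10, na)])
        i2 = toy_interface(rng.uniform(0, 15, (nb, 3)), rng.uniform(0, 15, (3, 3)),
                           aas_a=[aas[i] for i in rng.integers(0, 10, nb)])
        t = pc.RigidTransform.identity()
        pairs = optimal_matching(i1, i2, t)
        total_a = sum(p.eq_score for p in pairs if p.idx1 < na)
        # brute force over all injections of the smaller A-side into the larger
        w = np.zeros((na, nb))
        for i in range(na):
            for j in range(nb):
                d = np.linalg.norm(i1.residues[i].ca - i2.residues[j].ca)
                same = int(i1.residues[i].chem.label is i2.residues[j].chem.label)
                w[i, j] = equivalence_score(d, same)
        best = 0.0
        if na <= nb:
            for perm in itertools.permutations(range(nb), na):
                best = max(best, sum(w[i, perm[i]] for i in range(na)))
        else:
            for perm in itertools.permutations(range(na), nb):
                best = max(best, sum(w[perm[j], j] for j in range(nb)))
        assert total_a == pytest.approx(best, abs=1e-9)

    def test_fragments_never_cross(self, small_interface):
        moved, t = pc.apply_random_rigid(small_interface, 3)
        pairs = optimal_matching(small_interface, moved, t.inverse())
        frag1 = small_interface.fragments
        frag2 = moved.fragments
        assert all(frag1[p.idx1] == frag2[p.idx2] for p in pairs)


class TestKabsch:
    def test_identical_points_give_identity(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, (6, 3))
        t = kabsch_superpose(list(zip(x, x)))
        assert t.angle < 1e-9
        assert np.linalg.norm(t.translation) < 1e-9

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, (8, 3))
        R = Rotation.from_rotvec(np.radians(47) * np.array([1, 2, 2]) / 3.0).as_matrix()
        truth = pc.RigidTransform(R, np.array([1.0, -3.0, 2.5]))
        y = truth.apply(x)
        rec = kabsch_superpose(list(zip(y, x)))  # maps x back onto y
        ang, shift = rec.distance_to(truth)
        assert ang < 1e-8 and shift < 1e-8
        resid = np.linalg.norm(y - rec.apply(x))
        assert resid < 1e-8

    def test_mirror_guard_returns_proper_rotation(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, (8, 3))
        y = x * np.array([-1.0, 1.0, 1.0])  # reflected copy
        t = kabsch_superpose(list(zip(x, y)))
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(x - t.apply(y)) > 1.0  # reflection is unreachable

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose([(np.zeros(3), np.zeros(3))] * 2)
        line = [np.array([float(k), 0, 0]) for k in range(5)]
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(list(zip(line, line)))

    def test_beats_random_transforms(self):
        """The Kabsch fit is at least as good as any random rigid transform."""
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, (10, 3))
        y = x + rng.normal(0, 1.0, (10, 3))
        t = kabsch_superpose(list(zip(x, y)))
        best = np.sum((x - t.apply(y)) ** 2)
        for _ in range(1000):
            R = Rotation.random(random_state=rng).as_matrix()
            tr = rng.uniform(-15, 15, 3)
            assert best <= np.sum((x - (y @ R.T + tr)) ** 2) + 1e-9


class TestRefineAlignment:
    def test_identity_candidate_on_copy_converges_immediately(self, small_interface):
        cand = Candidate(pc.RigidTransform.identity(), len(small_interface), "AA")
        t, pairs, iters, degen = pc.refine_alignment(small_interface, small_interface, cand)
        assert not degen
        assert iters <= 2
        assert len(pairs) == len(small_interface)
        assert all(p.d < 1e-9 for p in pairs)

    def test_recovers_ground_truth_from_top_candidate(self, medium_interface):
        moved, truth = pc.apply_random_rigid(medium_interface, 9)
        cand = pc.geometric_hash_candidates(medium_interface, moved)[0]
        t, pairs, _, degen = pc.refine_alignment(medium_interface, moved, cand)
        assert not degen
        rmsd = np.sqrt(np.mean([p.d ** 2 for p in pairs]))
        assert rmsd < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_refinement_never_hurts_the_objective(self, seed):
        """The converged summed equivalence score is at least the score of the
        initial candidate's own matching (refinement only improves)."""
        i1, i2 = pc.generate_unrelated_pair(8, 8, seed)
        cands = pc.geometric_hash_candidates(i1, i2)
        if not cands:
            pytest.skip("no candidate above the vote threshold for this seed")
        cand = cands[0]
        initial = sum(p.eq_score for p in optimal_matching(i1, i2, cand.transform,
                                                           cand.fragment_mapping))
        _, pairs, _, _ = pc.refine_alignment(i1, i2, cand)
        final = sum(p.eq_score for p in pairs)
        assert final >= initial - 1e-9

    def test_deterministic(self, small_interface):
        moved, _ = pc.apply_random_rigid(small_interface, 13)
        cand = pc.geometric_hash_candidates(small_interface, moved)[0]
        r1 = pc.refine_alignment(small_interface, moved, cand)
        r2 = pc.refine_alignment(small_interface, moved, cand)
        np.testing.assert_array_equal(r1[0].rotation, r2[0].rotation)
        assert [(p.idx1, p.idx2) for p in r1[1]] == [(p.idx1, p.idx2) for p in r2[1]]
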