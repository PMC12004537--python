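"""Superposition, pose metrics, benchmark aggregation, Butina dedup."""

import itertools

import numpy as np
import pytest

from mdmr.benchmark import (Pose, PoseSet, butina_dedup, centroid_metric,
                            evaluate_complexes, kabsch_align, pose_rmsd,
                            rank_diagnostics)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q


def quaternion_superpose(P, Q):
    """Independent oracle: Horn's quaternion method for optimal rotation."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    w, v = np.linalg.eigh(K)
    q = v[:, -1]
    a, b, c, d = q
    R = np.array([
        [a*a + b*b - c*c - d*d, 2*(b*c - a*d), 2*(b*d + a*c)],
        [2*(b*c + a*d), a*a - b*b + c*c - d*d, 2*(c*d - a*b)],
        [2*(b*d - a*c), 2*(c*d + a*b), a*a - b*b - c*c + d*d]])
    fitted = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q0) ** 2, axis=1))))
    return R, rmsd


class TestKabsch:
    def test_identical_sets_identity(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_align(P, P)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(12, 3)) * 5
        R0 = random_rotation(rng)
        Q = P @ R0.T + rng.uniform(-20, 20, 3)
        R, t, rmsd = kabsch_align(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(P @ R.T + t, Q, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        P = rng.normal(size=(10, 3)) * 3
        Q = rng.normal(size=(10, 3)) * 3
        R, t, rmsd = kabsch_align(P, Q)
        Rq, rmsd_q = quaternion_superpose(P, Q)
        assert rmsd == pytest.approx(rmsd_q, abs=1e-8)
        assert np.allclose(R, Rq, atol=1e-6)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            kabsch_align(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_align(line, line)


RING = np.array([[np.cos(a), np.sin(a), 0.0]
                 for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]) * 1.39
RING_ELEMENTS = ["C"] * 6


class TestPoseRMSD:
    def test_identical_pose_zero(self):
        assert pose_rmsd(RING_ELEMENTS, RING, RING_ELEMENTS, RING) == 0.0

    def test_uniform_translation_exact(self):
        moved = RING + np.array([2.0, 0.0, 0.0])
        assert pose_rmsd(RING_ELEMENTS, moved, RING_ELEMENTS, RING,
                         symmetry=False) == pytest.approx(2.0, abs=1e-12)

    def test_ring_rotation_zero_with_symmetry_only(self):
        relabeled = np.roll(RING, 1, axis=0)  # rotate atom labels around ring
        sym = pose_rmsd(RING_ELEMENTS, relabeled, RING_ELEMENTS, RING)
        naive = pose_rmsd(RING_ELEMENTS, relabeled, RING_ELEMENTS, RING,
                          symmetry=False)
        assert sym == pytest.approx(0.0, abs=1e-12)
        assert naive > 0.5

    def test_symmetry_rmsd_matches_permutation_brute_force(self):
        rng = np.random.default_rng(3)
        pose = RING + rng.normal(0, 0.3, RING.shape)
        got = pose_rmsd(RING_ELEMENTS, pose, RING_ELEMENTS, RING)
        # oracle: all atom bijections that preserve ring bonds
        best = np.inf
        for perm in itertools.permutations(range(6)):
            ok = all(abs((perm[i] - perm[(i + 1) % 6]) % 6) in (1, 5)
                     for i in range(6))
            if not ok:
                continue
            best = min(best, float(np.sqrt(np.mean(
                np.sum((pose[list(perm)] - RING) ** 2, axis=1)))))
        assert got == pytest.approx(best, abs=1e-12)

    def test_symmetry_never_exceeds_naive(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pose = RING + rng.normal(0, 1.0, RING.shape)
            assert (pose_rmsd(RING_ELEMENTS, pose, RING_ELEMENTS, RING)
                    <= pose_rmsd(RING_ELEMENTS, pose, RING_ELEMENTS, RING,
                                 symmetry=False) + 1e-12)

    def test_formula_mismatch_errors(self):
        with pytest.raises(ValueError, match="formula"):
            pose_rmsd(["C", "N"], np.zeros((2, 3)), ["C", "C"], np.zeros((2, 3)))


def helix_ca(n=15):
    t = np.arange(n)
    pts = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * t], axis=1)
    return {("R", int(i + 1), ""): pts[i] for i in range(n)}


class TestCentroidMetric:
    def test_identical_self_docking_zero(self):
        ca = helix_ca()
        lig = np.array([[5.0, 0, 5], [6.5, 0, 5], [5.5, 1, 5]])
        assert centroid_metric(lig, lig, ca, ca) == pytest.approx(0.0, abs=1e-12)

    def test_translated_pose_gives_exact_distance(self):
        ca = helix_ca()
        lig = np.array([[5.0, 0, 5], [6.5, 0, 5], [5.5, 1, 5]])
        moved = lig + np.array([0.0, 4.9, 0.0])
        assert centroid_metric(moved, lig, ca, ca) == pytest.approx(4.9, abs=1e-9)

    def test_invariant_under_joint_rigid_transform(self):
        rng = np.random.default_rng(8)
        ca = helix_ca()
        lig = np.array([[5.0, 0, 5], [6.5, 0, 5], [5.5, 1, 5]])
        pose = lig + rng.normal(0, 2, lig.shape)
        base = centroid_metric(pose, lig, ca, ca)
        R0, t0 = random_rotation(rng), rng.uniform(-30, 30, 3)
        ca_moved = {k: R0 @ v + t0 for k, v in ca.items()}
        pose_moved = pose @ R0.T + t0
        assert centroid_metric(pose_moved, lig, ca_moved, ca) == pytest.approx(
            base, abs=1e-6)

    def test_low_overlap_warns(self):
        ca = helix_ca(20)
        few = {k: ca[k] for k in list(ca)[:4]}
        lig = np.array([[5.0, 0, 5], [6.5, 0, 5], [5.5, 1, 5]])
        with pytest.warns(UserWarning, match="shared"):
            centroid_metric(lig, lig, few, ca)


def pose_set(best_rmsds, cid="c0", mode="orthosteric"):
    """Pose set of toy 3-atom ligands with prescribed displacement.

    Coordinates are binary-representable so pure translations give exact
    metrics (a displacement of 2.0 yields RMSD exactly 2.0, testing the
    strictness of the < threshold)."""
    ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.25, 1.25, 0]])
    poses = [Pose(["C", "C", "O"], ref + np.array([d, 0, 0]), score=-r, rank=r)
             for r, d in enumerate(best_rmsds, start=1)]
    ca = helix_ca()
    return PoseSet(complex_id=cid, receptor_id="r", ligand_id="l",
                   binding_mode=mode, poses=poses,
                   ref_elements=["C", "C", "O"], ref_coords=ref,
                   ref_receptor_ca=ca, docked_receptor_ca=ca)


class TestEvaluateComplexes:
    def test_strict_threshold_fraction(self):
        sets = [pose_set([d], cid=f"c{i}")
                for i, d in enumerate([1.2, 1.9, 2.0, 3.5])]
        res = evaluate_complexes(sets, rule="self")
        assert res.group_fractions["orthosteric"] == pytest.approx(0.5)
        assert res.group_sizes["orthosteric"] == 4

    def test_top_k_rank_gating(self):
        ps = pose_set([5.0, 6.0, 1.0])  # only rank-3 pose is sub-2 Å
        assert evaluate_complexes([ps], rule="self")\
            .per_complex["c0"]["success"]
        assert not evaluate_complexes([ps], rule="self", top_k=1)\
            .per_complex["c0"]["success"]

    def test_success_monotone_in_top_k(self):
        rng = np.random.default_rng(12)
        sets = [pose_set(rng.uniform(0, 8, 6).tolist(), cid=f"c{i}")
                for i in range(12)]
        f1 = evaluate_complexes(sets, rule="self", top_k=1).overall_fraction
        f5 = evaluate_complexes(sets, rule="self", top_k=5).overall_fraction
        fu = evaluate_complexes(sets, rule="self").overall_fraction
        assert f1 <= f5 <= fu

    def test_cross_rule_uses_centroid_threshold(self):
        sets = [pose_set([4.0], cid="a"), pose_set([6.0], cid="b")]
        res = evaluate_complexes(sets, rule="cross")
        assert res.per_complex["a"]["success"]
        assert not res.per_complex["b"]["success"]

    def test_modes_grouped_separately_and_empty_absent(self):
        sets = [pose_set([1.0], cid="a", mode="orthosteric"),
                pose_set([9.0], cid="b", mode="allosteric")]
        res = evaluate_complexes(sets, rule="self")
        assert res.group_fractions == {"orthosteric": 1.0, "allosteric": 0.0}
        assert "typeIV" not in res.group_fractions


class TestRankDiagnostics:
    def test_hand_evaluated_case(self):
        # rank 1 correct and alone; ranks 2-5 one incorrect cluster
        ps = pose_set([0.1, 30.0, 30.2, 30.4, 30.6])
        d = rank_diagnostics(ps, rule="self")
        assert d.delta_pop == 1 - 4
        assert d.delta_rank == 2 - 1

    def test_all_correct_absent(self):
        assert rank_diagnostics(pose_set([0.1, 0.2, 0.3]), rule="self") is None

    def test_duplicate_correct_pose_grows_population(self):
        base = rank_diagnostics(pose_set([0.1, 30.0, 30.2, 30.4, 30.6]),
                                rule="self")
        more = rank_diagnostics(pose_set([0.1, 30.0, 30.2, 30.4, 30.6, 0.15]),
                                rule="self")
        assert more.delta_pop == base.delta_pop + 1
        assert more.delta_rank == base.delta_rank


def butina_reference(dm, threshold):
    """Independent restatement of the sphere-exclusion definition."""
    n = dm.shape[0]
    alive = list(range(n))
    clusters = []
    while alive:
        neigh = {i: [j for j in alive if j != i and dm[i, j] <= threshold]
                 for i in alive}
        best = sorted(alive, key=lambda i: (-len(neigh[i]), i))[0]
        members = [best] + sorted(neigh[best])
        clusters.append((best, members))
        alive = [i for i in alive if i not in members]
    return clusters


class TestButina:
    def test_identical_conformers_single_cluster(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 3)) * 3
        reps, clusters = butina_dedup([base.copy() for _ in range(6)], 2.0)
        assert len(clusters) == 1 and len(clusters[0]) == 6

    def test_all_distant_conformers_singletons(self):
        rng = np.random.default_rng(1)
        confs = []
        for _ in range(5):
            c = rng.normal(size=(6, 3)) * 4  # random internal geometry
            confs.append(c)
        reps, clusters = butina_dedup(confs, threshold=0.01)
        assert all(len(c) == 1 for c in clusters)

    def test_matches_reference_implementation_on_12_conformers(self):
        rng = np.random.default_rng(2)
        # three families of internal geometry, plus random rigid placement
        families = [rng.normal(size=(7, 3)) * 3 for _ in range(3)]
        confs = []
        for i in range(12):
            fam = families[i % 3]
            c = fam + rng.normal(0, 0.2, fam.shape)
            R = random_rotation(rng)
            confs.append(c @ R.T + rng.uniform(-50, 50, 3))
        reps, clusters = butina_dedup(confs, threshold=2.0)
        # rebuild the aligned-RMSD matrix independently
        n = len(confs)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                _, rq = quaternion_superpose(confs[i], confs[j])
                dm[i, j] = dm[j, i] = rq
        expected = butina_reference(dm, 2.0)
        assert list(zip(reps, clusters)) == expected

    def test_mismatched_atom_counts_error(self):
        with pytest.raises(ValueError, match="atom count"):
            butina_dedup([np.zeros((4, 3)), np.zeros((5, 3))])
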