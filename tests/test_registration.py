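"""Rigid correspondence solve, trimmed ICP, pairwise and chained reassembly."""

import numpy as np
import pytest

import vrakit as vk
from vrakit.registration import (
    IcpParams,
    MatchPlan,
    MatchStep,
    RegistrationError,
    _select_near,
)
from vrakit.synthetic import build_match_plan, pose_recovery_errors
from conftest import random_rigid


def _angle_deg(rot):
    return np.degrees(np.arccos(np.clip((np.trace(rot) - 1) / 2, -1, 1)))


class TestRigidFromCorrespondences:
    def test_identity(self, rng):
        pts = rng.normal(size=(5, 3))
        t = vk.rigid_from_correspondences(pts, pts)
        np.testing.assert_allclose(t.as_matrix(), np.eye(4), atol=1e-12)

    def test_exact_recovery(self, rng):
        """Constructive oracle: mov = T⁻¹(ref) recovers T to machine precision."""
        for _ in range(20):
            t = random_rigid(rng)
            ref = rng.normal(size=(6, 3)) * 30
            mov = t.inverse().apply(ref)
            got = vk.rigid_from_correspondences(ref, mov)
            assert np.abs(got.as_matrix() - t.as_matrix()).max() < 1e-9

    def test_cross_check_against_scipy(self, rng):
        """Independent oracle: scipy's Kabsch solver agrees on noisy pairs."""
        from scipy.spatial.transform import Rotation

        ref = rng.normal(size=(8, 3)) * 10
        mov = random_rigid(rng).apply(ref) + rng.normal(0, 0.1, (8, 3))
        got = vk.rigid_from_correspondences(ref, mov)
        rc, mc = ref - ref.mean(0), mov - mov.mean(0)
        rot_sp, _ = Rotation.align_vectors(rc, mc)
        np.testing.assert_allclose(got.rotation, rot_sp.as_matrix(), atol=1e-8)

    def test_noisy_solution_is_a_local_optimum(self, rng):
        """The returned fit beats 10^4 random perturbations of itself."""
        ref = rng.normal(size=(4, 3)) * 20
        mov = random_rigid(rng).apply(ref) + rng.normal(0, 0.3, (4, 3))
        t = vk.rigid_from_correspondences(ref, mov)
        best = np.sum((t.apply(mov) - ref) ** 2)
        for _ in range(10_000):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(-0.05, 0.05)
            k = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
            pert = vk.RigidTransform(rot @ t.rotation, t.translation + rng.normal(0, 0.02, 3))
            assert np.sum((pert.apply(mov) - ref) ** 2) >= best - 1e-9

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(RegistrationError):
            vk.rigid_from_correspondences(line, line + [0, 1, 0])

    def test_too_few_pairs(self, rng):
        pts = rng.normal(size=(2, 3))
        with pytest.raises(RegistrationError):
            vk.rigid_from_correspondences(pts, pts)


def _rough_patch(rng, n=600, extent=15.0):
    """A compact jagged surface patch for ICP exercises."""
    pts = rng.uniform(-extent, extent, size=(n, 2))
    z = np.sin(pts[:, 0] / 2.5) * np.cos(pts[:, 1] / 3.0) * 2.0
    return vk.PointCloud(np.column_stack([pts, z]))


class TestIcpRefine:
    def test_prealigned_converges_immediately(self, rng):
        ref = _rough_patch(rng)
        out = vk.icp_refine(ref, ref.copy())
        assert out.iterations <= 2
        assert out.final_rms < 1e-9
        assert out.converged

    def test_recovers_small_perturbation(self, rng):
        """5 degrees + 3 mm on an identical cloud -> near-exact recovery."""
        ref = _rough_patch(rng)
        axis = np.array([0.2, -0.5, 1.0])
        axis /= np.linalg.norm(axis)
        ang = np.deg2rad(5.0)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
        true = vk.RigidTransform(rot, np.array([1.5, -2.0, 1.8]))
        mov = vk.apply_transform(ref, true.inverse())
        out = vk.icp_refine(ref, mov, params=IcpParams(max_corr_dist=10.0))
        err = out.transform.compose(true.inverse())
        assert _angle_deg(err.rotation) < 0.1
        assert np.linalg.norm(err.translation) < 0.05

    def test_trimmed_rms_monotone_over_seeds(self):
        """Without a distance gate, the trimmed objective never increases."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            ref = _rough_patch(r)
            t = random_rigid(r)
            # moderate perturbation about the patch centroid
            c = ref.points.mean(axis=0)
            small = vk.RigidTransform(t.rotation @ t.rotation.T, np.zeros(3))  # identity
            mov = vk.PointCloud(ref.points + r.normal(0, 0.4, ref.points.shape))
            out = vk.icp_refine(
                ref,
                mov,
                params=IcpParams(max_corr_dist=1e9, trim_keep_fraction=0.8, max_iter=25),
            )
            diffs = np.diff(out.rms_history)
            assert np.all(diffs <= 1e-9)

    def test_no_correspondences_raises(self, rng):
        ref = _rough_patch(rng)
        far = vk.PointCloud(ref.points + 500.0)
        with pytest.raises(RegistrationError):
            vk.icp_refine(ref, far, params=IcpParams(max_corr_dist=1.0))


class TestMatchPlan:
    def _plan(self):
        return MatchPlan(
            [
                MatchStep(
                    ref_id="a",
                    mov_id="b",
                    ref_points=np.eye(3) * 2,
                    mov_points=np.eye(3) * 2 + 1,
                    icp_overrides={"trim_keep_fraction": 0.6},
                    surface_radius=12.0,
                    surface_band=3.0,
                )
            ]
        )

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_roundtrip(self, tmp_path, suffix):
        plan = self._plan()
        p = tmp_path / f"plan{suffix}"
        plan.to_file(p)
        back = MatchPlan.from_file(p)
        step = back.steps[0]
        assert step.ref_id == "a" and step.mov_id == "b"
        np.testing.assert_allclose(step.mov_points, plan.steps[0].mov_points)
        assert step.icp_overrides == {"trim_keep_fraction": 0.6}
        assert step.surface_radius == 12.0 and step.surface_band == 3.0

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(ValueError):
            MatchStep("a", "b", np.zeros((2, 3)), np.zeros((2, 3)))


class TestReassociatePair:
    def test_null_move_is_concatenation(self, rng):
        frag = _rough_patch(rng)
        surf = vk.segment_fracture(
            vk.PointCloud(frag.points, scalar=np.ones(len(frag)) * 2.0)
        )
        landmarks = frag.points[:4]
        merged, result = vk.reassociate_pair(
            frag, frag.copy(), surf, surf, landmarks, landmarks
        )
        assert len(merged) == 2 * len(frag)
        assert _angle_deg(result.transform.rotation) < 1e-6
        assert np.linalg.norm(result.transform.translation) < 1e-6

    def test_merged_count_always_sum(self, rng):
        a = vk.PointCloud(rng.normal(size=(40, 3)))
        b = vk.PointCloud(rng.normal(size=(25, 3)) + 0.5)
        surf_a = vk.segment_fracture(vk.PointCloud(a.points, scalar=np.ones(40)))
        surf_b = vk.segment_fracture(vk.PointCloud(b.points, scalar=np.ones(25)))
        merged, _ = vk.reassociate_pair(
            a, b, surf_a, surf_b, a.points[:4], b.points[:4],
            params=IcpParams(max_corr_dist=50.0),
        )
        assert len(merged) == 65


class TestReassemble:
    def test_empty_plan_is_noop(self, fractured_small_bone):
        fragments, truth = fractured_small_bone
        surfaces = {
            fid: vk.segment_fracture(vk.roughness(c)) for fid, c in fragments.items()
        }
        result = vk.reassemble(fragments, surfaces, MatchPlan([]))
        assert result.n_reassociated == 0
        assert len(result.merged) == len(fragments)
        for t in result.poses.values():
            np.testing.assert_allclose(t.as_matrix(), np.eye(4), atol=0)

    def test_parameter_recovery_three_fragment_bone(self):
        """Correct plan on a 3-fragment bone recovers every scatter pose."""
        bone = vk.make_long_bone(seed=3)
        fragments, truth = vk.fracture(bone, 3, seed=9, n_surface_points=15_000)
        surfaces = {
            fid: vk.segment_fracture(vk.roughness(c)) for fid, c in fragments.items()
        }
        plan = build_match_plan(fragments, truth, seed=5)
        result = vk.reassemble(fragments, surfaces, plan, refine_sweeps=2)
        assert result.n_reassociated == len(fragments) - 1
        ref_id = max(result.merged, key=lambda k: len(result.merged[k]))
        errors = pose_recovery_errors(result, truth, fragments, ref_id)
        worst_rot = max(a for a, _ in errors.values())
        worst_tr = max(t for _, t in errors.values())
        assert worst_rot < 0.5
        assert worst_tr < 0.5

    def test_unmatchable_step_flagged_and_others_unaffected(self, fractured_small_bone):
        fragments, truth = fractured_small_bone
        surfaces = {
            fid: vk.segment_fracture(vk.roughness(c)) for fid, c in fragments.items()
        }
        plan = build_match_plan(fragments, truth, seed=5)
        ids = list(fragments)
        # an orphan declaration: landmarks nowhere near any real surface
        bogus = MatchStep(
            ref_id=ids[0],
            mov_id=ids[-1],
            ref_points=np.eye(3) * 1e4,
            mov_points=np.eye(3) * -1e4,
        )
        mangled = MatchPlan(plan.steps[:2] + [bogus])
        result = vk.reassemble(fragments, surfaces, mangled, refine_sweeps=0)
        flags = [r.success for r in result.steps]
        assert flags[:2] == [True, True]
        assert result.steps[2].success is False
        assert result.steps[2].error is not None

    def test_equivariance_under_common_rigid_motion(self, fractured_small_bone, rng):
        """A common rigid motion of all inputs conjugates every pose.

        Short ICP runs are used: the algorithm is exactly equivariant in
        real arithmetic, but long trimmed runs can flip a correspondence
        at a selection boundary under floating-point perturbation and
        then follow a slightly different (equally valid) path.
        """
        fragments, truth = fractured_small_bone
        surfaces = {
            fid: vk.segment_fracture(vk.roughness(c)) for fid, c in fragments.items()
        }
        plan = build_match_plan(fragments, truth, seed=5)
        overrides = {"trim_keep_fraction": 0.5, "max_iter": 2}

        def remapped(transform_points):
            return MatchPlan(
                [
                    MatchStep(
                        s.ref_id,
                        s.mov_id,
                        transform_points(s.ref_points),
                        transform_points(s.mov_points),
                        icp_overrides=overrides,
                        surface_radius=s.surface_radius,
                        surface_band=s.surface_band,
                    )
                    for s in plan.steps
                ]
            )

        res1 = vk.reassemble(fragments, surfaces, remapped(lambda p: p), refine_sweeps=0)
        g = random_rigid(rng)
        fragments2 = {f: vk.apply_transform(c, g) for f, c in fragments.items()}
        surfaces2 = {
            fid: vk.FractureSurface(vk.apply_transform(s.cloud, g), s.threshold_used)
            for fid, s in surfaces.items()
        }
        res2 = vk.reassemble(fragments2, surfaces2, remapped(g.apply), refine_sweeps=0)
        for fid in res1.poses:
            expected = g.compose(res1.poses[fid]).compose(g.inverse())
            assert np.abs(res2.poses[fid].as_matrix() - expected.as_matrix()).max() < 1e-6

    def test_pose_manifest_serialisable(self, fractured_small_bone):
        import json

        fragments, truth = fractured_small_bone
        surfaces = {
            fid: vk.segment_fracture(vk.roughness(c)) for fid, c in fragments.items()
        }
        plan = build_match_plan(fragments, truth, seed=5)
        result = vk.reassemble(fragments, surfaces, plan)
        doc = json.dumps(result.pose_manifest())
        assert "poses" in doc


def test_select_near_band_and_radius(rng):
    cloud = vk.PointCloud(rng.uniform(-10, 10, size=(500, 3)))
    landmarks = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [5, 5, 0]], dtype=float)
    sel = _select_near(cloud, landmarks, radius=6.0, band=1.0)
    assert np.all(np.abs(sel.points[:, 2]) <= 1.0 + 1e-9)
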