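"""Core geometry: mesh I/O, subsampling, rigid transforms, NN distances."""

import numpy as np
import pytest
import trimesh

import vrakit as vk
from vrakit.geometry import MeshFormatError, concatenate
from conftest import random_rigid

ONE_TRIANGLE_STL = """solid tri
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
endsolid tri
"""


class TestMeshIO:
    def test_ascii_stl_single_triangle(self, tmp_path):
        p = tmp_path / "tri.stl"
        p.write_text(ONE_TRIANGLE_STL)
        mesh = vk.load_mesh(p)
        assert len(mesh.vertices) == 3
        assert len(mesh.faces) == 1

    def test_binary_and_ascii_stl_agree(self, tmp_path):
        """The same cube written in both STL dialects loads to one vertex set."""
        cube = trimesh.creation.box(extents=(1, 1, 1))
        pb, pa = tmp_path / "cube_b.stl", tmp_path / "cube_a.stl"
        cube.export(str(pb))  # binary by default
        pa.write_bytes(trimesh.exchange.stl.export_stl_ascii(cube).encode())
        vb = vk.load_mesh(pb).vertices
        va = vk.load_mesh(pa).vertices
        order = lambda v: v[np.lexsort(v.T)]
        np.testing.assert_allclose(order(vb), order(va), atol=1e-6)

    def test_cube_roundtrip(self, tmp_path):
        cube = trimesh.creation.box(extents=(2, 2, 2))
        p = tmp_path / "cube.stl"
        vk.save_mesh(cube, p)
        back = vk.load_mesh(p)
        assert len(back.vertices) == 8
        assert len(back.faces) == 12

    def test_stl_roundtrip_tolerance(self, tmp_path, small_bone):
        p = tmp_path / "bone.stl"
        vk.save_mesh(small_bone, p)
        back = vk.load_mesh(p)
        order = lambda v: v[np.lexsort(np.round(v, 4).T)]
        np.testing.assert_allclose(
            order(np.asarray(back.vertices)),
            order(np.asarray(small_bone.vertices)),
            atol=1e-4,  # binary STL stores 32-bit floats
        )

    def test_empty_mesh_refused(self, tmp_path):
        empty = trimesh.Trimesh()
        p = tmp_path / "empty.stl"
        with pytest.raises(ValueError):
            vk.save_mesh(empty, p)
        assert not p.exists()

    def test_truncated_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_bytes(b"\x00" * 50)
        with pytest.raises(MeshFormatError):
            vk.load_mesh(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshFormatError):
            vk.load_mesh(tmp_path / "nope.stl")


class TestCloudPly:
    def test_scalar_roundtrip_exact(self, tmp_path, rng):
        cloud = vk.PointCloud(rng.normal(size=(40, 3)), scalar=rng.random(40))
        p = tmp_path / "c.ply"
        vk.save_cloud_ply(cloud, p, "roughness")
        back = vk.load_cloud_ply(p)
        np.testing.assert_array_equal(back.points, cloud.points)
        np.testing.assert_array_equal(back.scalar, cloud.scalar)


class TestSubsample:
    @pytest.mark.parametrize("n", [1, 2, 1000])
    @pytest.mark.parametrize("mode", ["random_area_weighted", "homogeneous"])
    def test_exact_count_and_determinism(self, small_bone, n, mode):
        a = vk.subsample(small_bone, n, seed=3, mode=mode)
        b = vk.subsample(small_bone, n, seed=3, mode=mode)
        assert len(a) == n
        np.testing.assert_array_equal(a.points, b.points)

    def test_planar_containment(self):
        square = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]],
        )
        cloud = vk.subsample(square, 10, seed=0)
        assert np.all(cloud.points[:, :2] >= 0) and np.all(cloud.points[:, :2] <= 1)
        np.testing.assert_allclose(cloud.points[:, 2], 0, atol=1e-12)

    def test_area_weighting_binomial(self):
        """Triangles with area ratio 9:1 receive samples in that ratio."""
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [9, 0, 0], [0, 2, 0], [9, 2, 0], [10, 0, 0]],
            faces=[[0, 1, 2], [1, 4, 3]],
        )
        areas = mesh.area_faces
        p = areas[0] / areas.sum()
        cloud = vk.subsample(mesh, 10_000, seed=5)
        on_large = np.sum(cloud.points[:, 0] + cloud.points[:, 1] * 4.5 < 9)
        # count of x+4.5y<9 ~ membership of the big triangle
        expect = 10_000 * p
        sigma = np.sqrt(10_000 * p * (1 - p))
        assert abs(on_large - expect) < 3 * sigma

    def test_invalid_count(self, small_bone):
        with pytest.raises(ValueError):
            vk.subsample(small_bone, 0, seed=0)


class TestRigidTransform:
    def test_identity_and_translation(self):
        cloud = vk.PointCloud([[0.0, 0.0, 0.0]])
        assert np.allclose(
            vk.apply_transform(cloud, vk.RigidTransform.identity()).points, 0
        )
        t = vk.RigidTransform(np.eye(3), [1, 2, 3])
        np.testing.assert_allclose(vk.apply_transform(cloud, t).points, [[1, 2, 3]])

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            vk.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection
        with pytest.raises(ValueError):
            vk.RigidTransform(2 * np.eye(3), np.zeros(3))

    def test_compose_matches_matrix_product(self, rng):
        for _ in range(10):
            t1, t2 = random_rigid(rng), random_rigid(rng)
            pts = rng.normal(size=(30, 3))
            via_compose = t2.compose(t1).apply(pts)
            sequential = t2.apply(t1.apply(pts))
            assert np.abs(via_compose - sequential).max() < 1e-9

    def test_inverse_closure(self, rng):
        for _ in range(10):
            t = random_rigid(rng)
            m = t.compose(t.inverse()).as_matrix()
            np.testing.assert_allclose(m, np.eye(4), atol=1e-10)

    def test_pairwise_distances_preserved(self, rng):
        pts = rng.normal(size=(50, 3)) * 20
        cloud = vk.PointCloud(pts)
        t = random_rigid(rng)
        moved = vk.apply_transform(cloud, t).points
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_scalar_and_parent_carried(self, rng):
        cloud = vk.PointCloud(
            rng.normal(size=(5, 3)), scalar=np.arange(5.0), parent_index=np.arange(5)
        )
        out = vk.apply_transform(cloud, random_rigid(rng))
        np.testing.assert_array_equal(out.scalar, cloud.scalar)
        np.testing.assert_array_equal(out.parent_index, cloud.parent_index)


class TestNearestDistances:
    def test_self_distance_zero(self, rng):
        cloud = vk.PointCloud(rng.normal(size=(64, 3)))
        assert vk.nearest_distances(cloud, cloud).max() == 0.0

    def test_matches_brute_force(self, rng):
        a = vk.PointCloud(rng.normal(size=(100, 3)) * 10)
        b = vk.PointCloud(rng.normal(size=(100, 3)) * 10)
        fast = vk.nearest_distances(a, b)
        brute = np.linalg.norm(a.points[:, None] - b.points[None], axis=2).min(axis=1)
        np.testing.assert_allclose(fast, brute, atol=1e-12)

    def test_point_to_plane(self, rng):
        g = np.linspace(-5, 5, 40)
        xx, yy = np.meshgrid(g, g)
        plane = vk.PointCloud(np.stack([xx.ravel(), yy.ravel(), 0 * xx.ravel()], 1))
        q = vk.PointCloud([[0.0, 0.0, 2.0]])
        assert vk.nearest_distances(q, plane)[0] == pytest.approx(2.0, abs=0.05)

    def test_empty_reference_rejected(self, rng):
        a = vk.PointCloud(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError):
            vk.nearest_distances(a, vk.PointCloud(np.empty((0, 3))))


def test_concatenate_preserves_scalar(rng):
    a = vk.PointCloud(rng.normal(size=(4, 3)), scalar=np.ones(4))
    b = vk.PointCloud(rng.normal(size=(6, 3)), scalar=np.zeros(6))
    merged = concatenate([a, b])
    assert len(merged) == 10
    assert merged.scalar.sum() == 4
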