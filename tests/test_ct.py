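"""CT volume I/O, competitive region growing, surface extraction, triage length."""

import numpy as np
import pytest
from scipy import ndimage

import vrakit as vk
from vrakit.ct import CtVolume, VolumeFormatError
from conftest import random_rigid


def _sphere_volume(r=10.0, spacing=0.5, hu_in=1500.0, hu_out=-1000.0, margin=2):
    n = int(2 * (r / spacing + margin)) + 1
    ax = (np.arange(n) - n // 2) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    vox = np.where(xx**2 + yy**2 + zz**2 <= r**2, hu_in, hu_out)
    return CtVolume(voxels=vox, spacing=np.full(3, spacing), origin=np.array([-(n // 2) * spacing] * 3))


class TestVolumeIO:
    def test_nrrd_roundtrip(self, tmp_path):
        vol = CtVolume(
            voxels=np.random.default_rng(0).normal(0, 100, (16, 12, 10)),
            spacing=np.array([0.5, 0.5, 0.5]),
            origin=np.array([1.0, -2.0, 3.0]),
        )
        p = tmp_path / "v.nrrd"
        vk.save_volume(vol, p)
        back = vk.load_volume(p)
        np.testing.assert_allclose(back.voxels, vol.voxels)
        np.testing.assert_allclose(back.spacing, vol.spacing)
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_nifti_roundtrip(self, tmp_path):
        vol = CtVolume(
            voxels=np.random.default_rng(1).integers(-1000, 2000, (8, 9, 10)).astype(float),
            spacing=np.array([1.0, 0.7, 0.4]),
            origin=np.zeros(3),
        )
        p = tmp_path / "v.nii.gz"
        vk.save_volume(vol, p)
        back = vk.load_volume(p)
        np.testing.assert_allclose(back.voxels, vol.voxels)
        np.testing.assert_allclose(back.spacing, vol.spacing)

    def test_dicom_series_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(2)
        vox = rng.integers(-1000, 2000, (12, 10, 8)).astype(float)
        vol = CtVolume(voxels=vox, spacing=np.array([0.6, 0.8, 1.2]), origin=np.array([5.0, 6.0, 7.0]))
        d = tmp_path / "series"
        vk.write_dicom_series(vol, d)
        assert len(list(d.iterdir())) == 8  # one file per axial slice
        back = vk.load_volume(d)
        np.testing.assert_array_equal(back.voxels, vox)
        np.testing.assert_allclose(back.spacing, vol.spacing)
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "v.xyz"
        p.write_text("nope")
        with pytest.raises(VolumeFormatError):
            vk.load_volume(p)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            CtVolume(voxels=np.zeros((2, 2, 2)), spacing=np.array([1, 0, 1]), origin=np.zeros(3))


class TestRegionGrow:
    def test_saturated_volume_single_seed(self):
        vol = CtVolume(np.full((6, 6, 6), 500.0), np.ones(3), np.zeros(3))
        mask = vk.region_grow(vol, [(0, 0, 0)], lower_hu=300)
        assert np.all(mask.labels == 1)

    def test_matches_connected_component_oracle(self):
        """One seed grows exactly one blob; counts equal scipy labelling."""
        rng = np.random.default_rng(3)
        vox = np.full((20, 20, 20), -1000.0)
        vox[2:8, 2:8, 2:8] = 1500.0   # blob A
        vox[12:18, 12:18, 12:18] = 1400.0  # blob B, disjoint
        vol = CtVolume(vox, np.ones(3), np.zeros(3))
        mask = vk.region_grow(vol, [(3, 3, 3)], lower_hu=300)
        labels_oracle, _ = ndimage.label(vox >= 300, structure=np.ones((3, 3, 3)))
        blob_a = labels_oracle == labels_oracle[3, 3, 3]
        np.testing.assert_array_equal(mask.labels == 1, blob_a)

    def test_competitive_split_of_touching_fragments(self):
        """Two touching blocks, one seed each: labels partition the bone."""
        vox = np.full((20, 10, 10), -1000.0)
        vox[2:18, 2:8, 2:8] = 1500.0  # one connected bar
        vol = CtVolume(vox, np.ones(3), np.zeros(3))
        mask = vk.region_grow(vol, [(3, 5, 5), (16, 5, 5)], lower_hu=300)
        bone = vox >= 300
        assert np.array_equal(mask.labels > 0, bone)  # full cover
        assert (mask.labels == 1).sum() > 0 and (mask.labels == 2).sum() > 0
        # competitive fronts meet near the middle of the bar
        xs = np.where(mask.labels == 1)[0]
        assert xs.max() <= 10

    def test_seed_order_permutes_labels_only(self):
        vox = np.full((20, 20, 6), -1000.0)
        vox[2:8, 2:8] = 1500.0
        vox[12:18, 12:18] = 1500.0
        vol = CtVolume(vox, np.ones(3), np.zeros(3))
        m1 = vk.region_grow(vol, [(3, 3, 3), (15, 15, 3)], lower_hu=300)
        m2 = vk.region_grow(vol, [(15, 15, 3), (3, 3, 3)], lower_hu=300)
        np.testing.assert_array_equal(m1.labels == 1, m2.labels == 2)
        np.testing.assert_array_equal(m1.labels == 2, m2.labels == 1)

    def test_seed_below_threshold_names_seed(self):
        vol = CtVolume(np.full((4, 4, 4), -1000.0), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError, match=r"\(1, 1, 1\)"):
            vk.region_grow(vol, [(1, 1, 1)], lower_hu=300)


class TestExtractSurface:
    def test_single_voxel_closed_mesh(self):
        """A lone interior voxel yields a closed mesh of positive volume.

        The iso-surface rounds a single voxel to the octahedron through
        its face-neighbour midpoints (volume (4/3)·0.5³ ≈ 0.17 of the
        voxel), so only closure, orientation and order of magnitude are
        asserted here; metric accuracy is covered by the sphere test.
        """
        vox = np.full((5, 5, 5), -1000.0)
        vox[2, 2, 2] = 1500.0
        vol = CtVolume(vox, np.ones(3), np.zeros(3))
        mask = vk.region_grow(vol, [(2, 2, 2)], lower_hu=300)
        mesh = vk.extract_surface(mask, 1, vol)
        assert mesh.is_watertight
        assert 0.1 < mesh.volume <= 1.0

    def test_sphere_area_within_five_percent(self):
        vol = _sphere_volume(r=10.0, spacing=0.5)
        seed = tuple(int(v) for v in np.array(vol.voxels.shape) // 2)
        mask = vk.region_grow(vol, [seed], lower_hu=300)
        mesh = vk.extract_surface(mask, 1, vol)
        assert mesh.is_watertight
        assert mesh.area == pytest.approx(4 * np.pi * 10.0**2, rel=0.05)

    def test_absent_label_rejected(self):
        vol = _sphere_volume(r=3, spacing=1.0)
        mask = vk.region_grow(vol, [tuple(int(v) for v in np.array(vol.voxels.shape) // 2)])
        with pytest.raises(ValueError):
            vk.extract_surface(mask, 5, vol)


class TestFragmentLength:
    def test_box_principal_length(self):
        import trimesh

        box = trimesh.creation.box(extents=(30.0, 5.0, 5.0))
        assert vk.fragment_length(box) == pytest.approx(30.0, abs=1e-9)

    def test_rotation_invariant(self, rng):
        import trimesh

        box = trimesh.creation.box(extents=(30.0, 5.0, 5.0))
        t = random_rigid(rng)
        rotated = box.copy()
        rotated.apply_transform(t.as_matrix())
        assert vk.fragment_length(rotated) == pytest.approx(30.0, abs=1e-6)

    def test_filter_by_length_default_two_centimetres(self):
        import trimesh

        long_frag = trimesh.creation.box(extents=(30.0, 5.0, 5.0))
        short_frag = trimesh.creation.box(extents=(15.0, 5.0, 5.0))
        kept = vk.filter_by_length([long_frag, short_frag])
        assert kept == [long_frag]
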