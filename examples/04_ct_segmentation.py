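"""CT round trip: voxelize a bone, segment it by seeded region growing,
extract the surface, and apply the 2 cm field-triage length rule."""
import numpy as np
import vrakit as vk

bone = vk.make_long_bone(length=120, shaft_radius=10, end_radius=16, seed=9,
                         n_axial=90, n_theta=64)
volume = vk.voxelize(bone, spacing=1.5, seed=9)          # HU grid
print(f"volume: {volume.voxels.shape} voxels at {volume.spacing[0]} mm")

seed_voxel = tuple(int(v) for v in np.argwhere(volume.voxels > 300)[0])
mask = vk.region_grow(volume, [seed_voxel], lower_hu=300)  # +300 HU bone threshold
mesh = vk.extract_surface(mask, 1, volume)
length = vk.fragment_length(mesh)
print(f"segmented mesh: watertight={mesh.is_watertight}, principal length={length:.1f} mm")
print(f"retained by the >= 20 mm triage rule: {length >= 20.0}")
# the mesh can now be saved as STL and subsampled to a working point cloud:
cloud = vk.subsample(mesh, 20_000, seed=1)
print(f"working cloud: {len(cloud)} points")
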