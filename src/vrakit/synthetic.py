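"""Ground-truthed synthetic long bones, fragmentation, and CT voxelization.

No imaging data is deposited with the laboratory study this package
operationalises, so validation runs on synthetic specimens that carry full
ground truth: a parametric long bone (surface of revolution with flared
ends), controlled fragmentation into shaft-transverse slabs with rough
fracture faces, per-fragment scatter poses, per-point cortical/fracture
labels, and a voxelizer producing CT-like attenuation volumes.

Fragmentation is modelled at point-cloud level: the densely sampled bone
surface is partitioned by random cut planes through the shaft — transverse
cuts into slabs plus longitudinal chord splits, the mixed pattern of a
comminuted fracture — and fracture-face points are synthesised on each cut
as a jittered in-plane grid displaced along the plane normal by a seeded
band-limited relief whose RMS is the requested fracture amplitude.  The
relief field of a cut is one continuous surface that both adjoining
fragments sample on their own grids, as the two sides of a real fracture
imaged by CT.  Ground-truth labels and poses come free, enabling the
parameter-recovery experiments that the physical study performed with
glue and a CT scanner.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh

from .ct import CtVolume
from .geometry import PointCloud, RigidTransform, subsample
from .registration import MatchPlan, MatchStep, ReassemblyResult

__all__ = [
    "GroundTruth",
    "make_long_bone",
    "fracture",
    "voxelize",
    "build_match_plan",
    "default_fragment_count",
    "pose_recovery_errors",
]

#: study-scale fragment counts: mean ~29 fragments per fragmented femur
FRAGMENT_COUNT_MEAN = 28.7
FRAGMENT_COUNT_SD = 7.8

#: default RMS fracture-face relief (mm); sized so that the jagged band of
#: the relief lifts a usable share of face points above the 1.0 mm
#: roughness threshold at the default plane-fit kernel
DEFAULT_FRACTURE_AMPLITUDE = 1.5


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _radius_profile(z: np.ndarray, length: float, shaft_radius: float, end_radius: float) -> np.ndarray:
    """Radius of revolution: shaft, smooth flares over the end 15%, and
    tangent-smooth rounded tips (quarter-ellipse caps) — no sharp edge
    where a flat cap would meet the flared side."""
    z = np.asarray(z, dtype=float)
    ramp = 0.15 * length
    zp = np.minimum(z, length - z)  # distance to the nearer end
    cap = 0.6 * end_radius
    flare = shaft_radius + (end_radius - shaft_radius) * _smoothstep(
        (ramp - zp) / max(ramp - cap, 1e-9)
    )
    with np.errstate(invalid="ignore"):
        tip = end_radius * np.sqrt(np.clip(1.0 - ((cap - zp) / cap) ** 2, 0.0, 1.0))
    return np.where(zp < cap, tip, flare)


def make_long_bone(
    length: float = 200.0,
    shaft_radius: float = 12.0,
    end_radius: float = 25.0,
    seed: int = 0,
    undulation: float = 0.02,
    n_axial: int = 160,
    n_theta: int = 96,
) -> trimesh.Trimesh:
    """Closed long-bone-like surface of revolution (dimensions in mm).

    A cylindrical shaft flares smoothly to ``end_radius`` over the
    terminal 15% of the length at both ends, with optional low-amplitude
    seeded surface undulation (< 0.05 mm) imitating cortical texture.
    The analytic radius profile is kept in ``mesh.metadata['long_bone']``
    so that downstream generators can perform exact inside tests.
    """
    if not (end_radius >= shaft_radius > 0):
        raise ValueError("require end_radius >= shaft_radius > 0")
    if length <= 4 * end_radius:
        raise ValueError("require length > 4 * end_radius")
    if not (0 <= undulation < 0.05):
        raise ValueError("undulation must be in [0, 0.05) mm")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, length, n_axial)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r = _radius_profile(z, length, shaft_radius, end_radius)[:, None]
    if undulation > 0:
        phases = rng.uniform(0, 2 * np.pi, size=(3, 2))
        zz, tt = np.meshgrid(z, theta, indexing="ij")
        wob = sum(
            np.sin(2 * np.pi * (k + 1) * zz / length + phases[k, 0])
            * np.cos((k + 2) * tt + phases[k, 1])
            for k in range(3)
        )
        r = r + undulation * wob / 3.0
    x = r * np.cos(theta)[None, :]
    y = r * np.sin(theta)[None, :]
    zs = np.repeat(z[:, None], n_theta, axis=1)
    ring = np.stack([x, y, zs], axis=-1).reshape(-1, 3)
    bottom = np.array([[0.0, 0.0, 0.0]])
    top = np.array([[0.0, 0.0, length]])
    vertices = np.vstack([ring, bottom, top])
    ib, it = len(ring), len(ring) + 1
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    for j in range(n_theta):  # end caps as fans to the pole vertices
        faces.append([ib, (j + 1) % n_theta, j])
        k = (n_axial - 1) * n_theta
        faces.append([it, k + j, k + (j + 1) % n_theta])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)
    mesh.metadata["long_bone"] = {
        "length": length,
        "shaft_radius": shaft_radius,
        "end_radius": end_radius,
    }
    mesh.metadata["units"] = "mm"
    return mesh


def _inside_fn(mesh: trimesh.Trimesh):
    """Point-in-solid test: analytic for generated bones, ray-cast otherwise."""
    lb = mesh.metadata.get("long_bone")
    if lb is not None:

        def inside(points: np.ndarray) -> np.ndarray:
            p = np.asarray(points, dtype=float)
            z = p[:, 2]
            rad = np.hypot(p[:, 0], p[:, 1])
            ok = (z >= 0) & (z <= lb["length"])
            r = _radius_profile(np.clip(z, 0, lb["length"]), lb["length"],
                                lb["shaft_radius"], lb["end_radius"])
            return ok & (rad <= r)

        return inside

    def ray_parity_inside(points: np.ndarray) -> np.ndarray:
        """Point-in-solid by +z ray-crossing parity (watertight meshes)."""
        p = np.asarray(points, dtype=float)
        tri = mesh.triangles  # (T, 3, 3)
        crossings = np.zeros(len(p), dtype=int)
        for v0, v1, v2 in tri:
            d1 = v1[:2] - v0[:2]
            d2 = v2[:2] - v0[:2]
            det = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(det) < 1e-15:
                continue  # triangle vertical w.r.t. the ray direction
            rel = p[:, :2] - v0[:2]
            a = (rel[:, 0] * d2[1] - rel[:, 1] * d2[0]) / det
            b = (d1[0] * rel[:, 1] - d1[1] * rel[:, 0]) / det
            hit = (a >= 0) & (b >= 0) & (a + b <= 1)
            if not hit.any():
                continue
            z_hit = v0[2] + a[hit] * (v1[2] - v0[2]) + b[hit] * (v2[2] - v0[2])
            above = z_hit > p[hit, 2]
            idx = np.where(hit)[0][above]
            crossings[idx] += 1
        return crossings % 2 == 1

    return ray_parity_inside


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows about a fragmented specimen.

    ``poses[fid]`` is the scatter transform taking the fragment from the
    intact (generator) frame to its delivered frame.  ``fracture_mask``
    flags fracture-face points; ``plane_id`` gives the cut plane each
    fracture point lies on and ``pair_id`` the fragment-pair interface it
    belongs to (−1 for cortical points).  ``adjacency`` lists
    ``(fragment_a, fragment_b, pair_id)`` for every surviving interface
    sampled robustly from both sides.
    """

    poses: dict[str, RigidTransform]
    fracture_mask: dict[str, np.ndarray]
    plane_id: dict[str, np.ndarray]
    pair_id: dict[str, np.ndarray]
    intact: PointCloud
    adjacency: list[tuple[str, str, int]]
    lost: list[str]
    params: dict
    seed: int

    def unscatter(self, fragments: dict[str, PointCloud]) -> dict[str, PointCloud]:
        """Map delivered fragments back to the intact frame (truth poses)."""
        from .geometry import apply_transform

        return {
            fid: apply_transform(cloud, self.poses[fid].inverse())
            for fid, cloud in fragments.items()
        }


def default_fragment_count(rng: np.random.Generator) -> int:
    """Draw a per-bone fragment count at the study's scale (mean ~29)."""
    return int(np.clip(round(rng.normal(FRAGMENT_COUNT_MEAN, FRAGMENT_COUNT_SD)), 2, None))


#: fraction of relief variance in the short-wavelength (jagged) band; the
#: rest is centimetre-scale waviness that gives registration a wide,
#: unambiguous basin of attraction
_SHORT_BAND_POWER = 0.64

#: wavelength bands (mm) of the fracture relief: millimetre-scale
#: jaggedness that carries the roughness signal, and large-scale waviness
_SHORT_BAND = (4.0, 8.0)
_LONG_BAND = (12.0, 30.0)


@dataclasses.dataclass
class _FractureRelief:
    """One continuous random relief field shared by both sides of a cut.

    A band-limited sum of random plane waves: a short-wavelength band
    (mm-scale jaggedness, the roughness signal a threshold can pick up)
    plus a long-wavelength band (cm-scale waviness, which makes the face
    globally non-self-similar so registration has a single wide optimum).
    Both fragments adjoining the cut sample this same field at their own
    grid points, as the two sides of a real fracture share one surface.
    """

    wavelength: np.ndarray
    direction: np.ndarray  # (K,) in-plane wave directions, radians
    phase: np.ndarray
    coefficient: np.ndarray

    @staticmethod
    def draw(amplitude: float, rng: np.random.Generator, extent: float) -> "_FractureRelief":
        n_short, n_long = 10, 4
        lam = np.concatenate(
            [rng.uniform(*_SHORT_BAND, n_short), rng.uniform(*_LONG_BAND, n_long)]
        )
        theta = rng.uniform(0, np.pi, n_short + n_long)
        phase = rng.uniform(0, 2 * np.pi, n_short + n_long)
        coef = rng.standard_normal(n_short + n_long)
        # normalise each band on a reference grid, then mix to RMS = amplitude
        g = np.linspace(-extent, extent, 61)
        aa, bb = np.meshgrid(g, g, indexing="ij")
        rel = _FractureRelief(lam, theta, phase, coef)
        short = rel._band(aa, bb, slice(0, n_short))
        long_ = rel._band(aa, bb, slice(n_short, None))
        coef = coef.copy()
        coef[:n_short] *= amplitude * np.sqrt(_SHORT_BAND_POWER) / max(np.std(short), 1e-12)
        coef[n_short:] *= amplitude * np.sqrt(1 - _SHORT_BAND_POWER) / max(np.std(long_), 1e-12)
        return _FractureRelief(lam, theta, phase, coef)

    def _band(self, a: np.ndarray, b: np.ndarray, sl: slice) -> np.ndarray:
        out = np.zeros_like(a, dtype=float)
        for lam, th, ph, c in zip(
            self.wavelength[sl], self.direction[sl], self.phase[sl], self.coefficient[sl]
        ):
            out += c * np.cos(2 * np.pi * (a * np.cos(th) + b * np.sin(th)) / lam + ph)
        return out

    def __call__(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self._band(a, b, slice(None))


def fracture(
    bone: trimesh.Trimesh,
    n_fragments: int,
    seed: int = 0,
    fracture_amplitude: float = DEFAULT_FRACTURE_AMPLITUDE,
    loss_fraction: float = 0.0,
    n_surface_points: int = 30_000,
    face_grid_spacing: float = 0.5,
    max_tilt_deg: float = 3.0,
    scatter_extent: float = 150.0,
) -> tuple[dict[str, PointCloud], GroundTruth]:
    """Fragment a bone into scattered point clouds with full ground truth.

    The bone surface is densely sampled and partitioned by
    ``n_fragments − 1`` seeded random cut planes through the shaft:
    transverse cuts (tilted up to ``max_tilt_deg``) divide the bone into
    slabs, and a longitudinal chord plane splits each slab in two — the
    mixed transverse/longitudinal pattern of a comminuted long-bone
    fracture, which yields chunky fragments whose broken faces are well
    separated (an all-transverse stack at study-scale fragment counts
    would produce millimetre wafers thinner than the fracture relief).

    Each cut carries one continuous band-limited relief field; the two
    fragments adjoining a cut sample that shared surface on their own
    jittered grids, as the two sides of a real fracture imaged by CT.
    Every fragment receives a random rigid scatter pose, recorded in the
    ground truth.  ``loss_fraction`` of the interior fragments is deleted
    to emulate the loss of intermediate elements seen after an explosion.
    """
    if n_fragments < 2:
        raise ValueError("n_fragments must be >= 2")
    if not (0.0 <= loss_fraction < 1.0):
        raise ValueError("loss_fraction must be in [0, 1)")
    lb = bone.metadata.get("long_bone")
    if lb is None:
        ext = bone.bounds
        length = ext[1, 2] - ext[0, 2]
    else:
        length = lb["length"]
    rng = np.random.default_rng(seed)
    intact = subsample(bone, n_surface_points, seed=int(rng.integers(2**31)))
    inside = _inside_fn(bone)
    rmax = (lb["end_radius"] if lb else float(np.abs(bone.vertices[:, :2]).max())) + 1.0

    n_sectors = 2 if n_fragments >= 6 else 1
    n_slabs = n_fragments // n_sectors
    n_extra = n_fragments - n_sectors * n_slabs  # slabs receiving one extra local split

    def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(normal, ref)
        u /= np.linalg.norm(u)
        return u, np.cross(normal, u)

    for _attempt in range(100):
        # transverse cuts -> slabs
        n_t = n_slabs - 1
        lo, hi = 0.12 * length, 0.88 * length
        if n_t > 0:
            base = np.linspace(lo, hi, n_t + 2)[1:-1]
            step = (hi - lo) / (n_t + 1)
            z_cuts = np.sort(base + rng.uniform(-0.3, 0.3, size=n_t) * step)
        else:
            z_cuts = np.zeros(0)
        tilt = np.deg2rad(rng.uniform(0, max_tilt_deg, size=n_t))
        azim = rng.uniform(0, 2 * np.pi, size=n_t)
        t_normals = np.stack(
            [np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)], axis=1
        ).reshape(n_t, 3)
        t_centres = np.stack([np.zeros(n_t), np.zeros(n_t), z_cuts], axis=1).reshape(n_t, 3)

        planes: list[dict] = [
            {"centre": t_centres[j], "normal": t_normals[j], "kind": "transverse"}
            for j in range(n_t)
        ]
        if n_sectors == 2:
            # one longitudinal chord plane through the whole shaft
            th = rng.uniform(0, 2 * np.pi)
            offset = rng.uniform(-4.0, 4.0)
            c_tilt = np.deg2rad(rng.uniform(0, max_tilt_deg))
            normal = np.array(
                [np.cos(th) * np.cos(c_tilt), np.sin(th) * np.cos(c_tilt), np.sin(c_tilt)]
            )
            centre = np.array([np.cos(th) * offset, np.sin(th) * offset, length / 2])
            planes.append({"centre": centre, "normal": normal, "kind": "chord"})
        local_slabs = (
            sorted(rng.choice(n_slabs, size=n_extra, replace=False).tolist())
            if n_extra
            else []
        )
        for sl in local_slabs:
            th = rng.uniform(0, 2 * np.pi)
            offset = rng.uniform(-4.0, 4.0)
            normal = np.array([np.cos(th), np.sin(th), 0.0])
            centre = np.array([np.cos(th) * offset, np.sin(th) * offset, length / 2])
            planes.append(
                {"centre": centre, "normal": normal, "kind": "local", "slab": sl}
            )

        def label_keys(points: np.ndarray) -> np.ndarray:
            """Fragment key per point: (slab, sector, local-sign) encoded."""
            pts = np.atleast_2d(points)
            if n_t > 0:
                signed = np.einsum(
                    "pjk,jk->pj", pts[:, None, :] - t_centres[None, :, :], t_normals
                )
                slab = (signed > 0).sum(axis=1)
            else:
                slab = np.zeros(len(pts), dtype=int)
            key = slab * 4
            if n_sectors == 2:
                ch = planes[n_t]
                key += ((pts - ch["centre"]) @ ch["normal"] > 0).astype(int) * 2
            for i, sl in enumerate(local_slabs):
                pl = planes[n_t + (n_sectors - 1) + i]
                in_slab = slab == sl
                key[in_slab] += (
                    (pts[in_slab] - pl["centre"]) @ pl["normal"] > 0
                ).astype(int)
            return key

        keys = label_keys(intact.points)
        uniq, counts = np.unique(keys, return_counts=True)
        if len(uniq) == n_fragments and counts.min() >= 30:
            break
    else:
        raise RuntimeError("could not draw cut planes intersecting the bone (100 attempts)")

    key_to_idx = {int(k): i for i, k in enumerate(uniq.tolist())}
    ids = [f"frag{k:02d}" for k in range(n_fragments)]

    # one continuous relief field per cut plane; each adjoining fragment
    # samples it on its own jittered grid (two samplings of one surface,
    # as with real CT clouds of the two sides of a fracture)
    reliefs = [_FractureRelief.draw(fracture_amplitude, rng, rmax) for _ in planes]

    face_parts: dict[int, list[tuple[np.ndarray, int, int]]] = {
        i: [] for i in range(n_fragments)
    }
    pair_index: dict[tuple[int, int], int] = {}
    pair_counts: dict[int, list[int]] = {}
    half_len = length / 2 + 2.0
    for p_idx, plane in enumerate(planes):
        n_hat = plane["normal"]
        u, v = plane_basis(n_hat)
        ext_u = half_len if plane["kind"] != "transverse" else rmax
        gu = np.arange(-ext_u, ext_u + face_grid_spacing, face_grid_spacing)
        gv = np.arange(-rmax, rmax + face_grid_spacing, face_grid_spacing)
        for side in (0, 1):
            aa, bb = np.meshgrid(gu, gv, indexing="ij")
            jitter = rng.uniform(-0.25, 0.25, size=(2,) + aa.shape) * face_grid_spacing
            aa = (aa + jitter[0]).ravel()
            bb = (bb + jitter[1]).ravel()
            base = plane["centre"] + aa[:, None] * u + bb[:, None] * v
            keep = inside(base)
            aa, bb, base = aa[keep], bb[keep], base[keep]
            klo = label_keys(base - 1e-3 * n_hat)
            khi = label_keys(base + 1e-3 * n_hat)
            valid = klo != khi
            if plane["kind"] == "local":
                sl = plane["slab"]
                valid &= (klo // 4 == sl) & (khi // 4 == sl)
            aa, bb, base = aa[valid], bb[valid], base[valid]
            klo, khi = klo[valid], khi[valid]
            disp = reliefs[p_idx](aa, bb)
            pts = base + disp[:, None] * n_hat
            own = klo if side == 0 else khi
            for ka, kb in {
                (int(x), int(y)) for x, y in zip(np.minimum(klo, khi), np.maximum(klo, khi))
            }:
                if ka not in key_to_idx or kb not in key_to_idx:
                    continue
                sel = (np.minimum(klo, khi) == ka) & (np.maximum(klo, khi) == kb)
                if sel.sum() < 20:
                    continue
                pair = (key_to_idx[ka], key_to_idx[kb])
                pid = pair_index.setdefault(pair, len(pair_index))
                pair_counts.setdefault(pid, [0, 0])[side] += int(sel.sum())
                for frag_key in {int(x) for x in own[sel]}:
                    if frag_key not in key_to_idx:
                        continue
                    sub = sel & (own == frag_key)
                    face_parts[key_to_idx[frag_key]].append(
                        (pts[sub], p_idx, pid)
                    )

    fragments: dict[str, PointCloud] = {}
    fracture_mask: dict[str, np.ndarray] = {}
    plane_id: dict[str, np.ndarray] = {}
    pair_id_map: dict[str, np.ndarray] = {}
    for k, fid in enumerate(ids):
        cortical = intact.points[keys == uniq[k]]
        parts = [cortical]
        pl = [np.full(len(cortical), -1, dtype=int)]
        pr = [np.full(len(cortical), -1, dtype=int)]
        for pts, p_idx, pid in face_parts[k]:
            parts.append(pts)
            pl.append(np.full(len(pts), p_idx, dtype=int))
            pr.append(np.full(len(pts), pid, dtype=int))
        fragments[fid] = PointCloud(np.vstack(parts))
        plane_id[fid] = np.concatenate(pl)
        pair_id_map[fid] = np.concatenate(pr)
        fracture_mask[fid] = plane_id[fid] >= 0

    # adjacency: pairs sampled robustly from both sides
    adjacency: list[tuple[str, str, int]] = []
    for (ia, ib), pid in sorted(pair_index.items(), key=lambda kv: kv[1]):
        ca, cb = pair_counts.get(pid, [0, 0])
        if ca >= 20 and cb >= 20:
            adjacency.append((ids[ia], ids[ib], pid))

    lost: list[str] = []
    slab_of = {ids[i]: int(uniq[i]) // 4 for i in range(n_fragments)}
    interior = [f for f in ids if 0 < slab_of[f] < n_slabs - 1]
    n_lose = int(round(loss_fraction * len(interior)))
    if n_lose > 0:
        lost = sorted(rng.choice(interior, size=n_lose, replace=False).tolist())
        for fid in lost:
            del fragments[fid], fracture_mask[fid], plane_id[fid], pair_id_map[fid]
        adjacency = [(a, b, p) for a, b, p in adjacency if a not in lost and b not in lost]

    poses: dict[str, RigidTransform] = {}
    for fid in list(fragments):
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, xq, yq, zq = q
        rot = np.array(
            [
                [1 - 2 * (yq**2 + zq**2), 2 * (xq * yq - zq * w), 2 * (xq * zq + yq * w)],
                [2 * (xq * yq + zq * w), 1 - 2 * (xq**2 + zq**2), 2 * (yq * zq - xq * w)],
                [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w), 1 - 2 * (xq**2 + yq**2)],
            ]
        )
        t = rng.uniform(-scatter_extent, scatter_extent, size=3)
        pose = RigidTransform(rot, t)
        poses[fid] = pose
        fragments[fid] = PointCloud(pose.apply(fragments[fid].points))

    truth = GroundTruth(
        poses=poses,
        fracture_mask=fracture_mask,
        plane_id=plane_id,
        pair_id=pair_id_map,
        intact=intact,
        adjacency=adjacency,
        lost=lost,
        params={
            "n_fragments": n_fragments,
            "fracture_amplitude": fracture_amplitude,
            "loss_fraction": loss_fraction,
            "n_surface_points": n_surface_points,
            "face_grid_spacing": face_grid_spacing,
            "max_tilt_deg": max_tilt_deg,
            "scatter_extent": scatter_extent,
        },
        seed=seed,
    )
    return fragments, truth


def _farthest_point_pick(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of k well-spread points (greedy farthest-point traversal)."""
    idx = [int(rng.integers(len(points)))]
    d = np.linalg.norm(points - points[idx[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(idx, dtype=np.intp)


def build_match_plan(
    fragments: dict[str, PointCloud],
    truth: GroundTruth,
    seed: int = 0,
    n_landmarks: int = 4,
    landmark_sigma: float = 0.25,
    trim_keep_fraction: float = 0.5,
    surface_radius: float = 15.0,
    surface_band: float = 3.5,
    polish_gate: float = 1.5,
) -> MatchPlan:
    """Synthetic operator: landmark correspondences for each adjacent pair.

    Emulates the manual steps of the protocol.  Landmarks are ~4 spots on
    the shared fracture surface, identified on *both* sides (the relief
    is one continuous surface, so a physical spot exists in each
    fragment's cloud) and jittered by isotropic Gaussian click noise of
    ``landmark_sigma`` mm; like a human operator the picker favours
    well-separated, distinctive spots (face corners), which bounds the
    coarse rotation error at a given click noise.

    Each step carries two operator judgements as overrides: the matching
    surface selection (only fracture points within ``surface_radius`` mm
    of the clicked landmarks take part in the refinement — the operator
    registers the two faces they matched, not every broken face of the
    fragment) and a trim of ``trim_keep_fraction`` (an interior fragment
    has two broken faces of which only one is shared, so at most about
    half of its fracture points can have true counterparts).

    Steps form a spanning tree of the fragment adjacency graph grown
    outwards from a central, well-connected fragment, preferring large
    interfaces — every new fragment is registered against an
    already-placed neighbour, and chains of compounded registrations are
    as short as the graph allows.
    """
    rng = np.random.default_rng(seed)
    # spanning tree over the fragment adjacency graph, grown outwards
    # from a central, well-connected fragment (Prim's algorithm with the
    # interface size as edge weight): every step registers a new fragment
    # against an already-placed neighbour, and chains of compounded
    # registrations stay as short as the graph allows
    weight: dict[tuple[str, str, int], int] = {}
    neighbours: dict[str, list[tuple[str, str, int]]] = {}
    for a, b, pid in truth.adjacency:
        if a not in fragments or b not in fragments:
            continue
        w = min(
            int(np.sum(truth.pair_id[a] == pid)), int(np.sum(truth.pair_id[b] == pid))
        )
        weight[(a, b, pid)] = w
        neighbours.setdefault(a, []).append((a, b, pid))
        neighbours.setdefault(b, []).append((a, b, pid))
    ordered: list[tuple[str, str, int]] = []
    remaining = set(neighbours)
    while remaining:
        root = max(remaining, key=lambda f: sum(weight[e] for e in neighbours[f]))
        visited = {root}
        remaining.discard(root)
        while True:
            best = None
            for f in visited:
                for a, b, pid in neighbours[f]:
                    other = b if a == f else a
                    if other in visited:
                        continue
                    if best is None or weight[(a, b, pid)] > weight[best[:3]]:
                        best = (a, b, pid, f, other)
            if best is None:
                break
            a, b, pid, ref, mov = best
            ordered.append((ref, mov, pid))
            visited.add(mov)
            remaining.discard(mov)
    steps = []
    for ref_id, mov_id, pid in ordered:
        ia = np.where(truth.pair_id[ref_id] == pid)[0]
        if len(ia) < n_landmarks:
            continue
        pick = _farthest_point_pick(fragments[ref_id].points[ia], n_landmarks, rng)
        spots = fragments[ref_id].points[ia[pick]]
        # the same physical surface spots, seen in the moving fragment's frame
        spots_mov = truth.poses[mov_id].apply(truth.poses[ref_id].inverse().apply(spots))
        ref_pts = spots + rng.normal(0, landmark_sigma, (n_landmarks, 3))
        mov_pts = spots_mov + rng.normal(0, landmark_sigma, (n_landmarks, 3))
        steps.append(
            MatchStep(
                ref_id=ref_id,
                mov_id=mov_id,
                ref_points=ref_pts,
                mov_points=mov_pts,
                icp_overrides={
                    "trim_keep_fraction": trim_keep_fraction,
                    "polish_gate": polish_gate,
                },
                surface_radius=surface_radius,
                surface_band=surface_band,
            )
        )
    return MatchPlan(steps)


def pose_recovery_errors(
    result: ReassemblyResult, truth: GroundTruth, fragments: dict[str, PointCloud], ref_id: str
) -> dict[str, tuple[float, float]]:
    """Rotation (deg) and translation (mm) error of each recovered pose.

    The assembly frame is the reference fragment's delivered frame, so the
    true pose of fragment f relative to the assembly is S_ref ∘ S_f⁻¹.
    The error transform is evaluated in the intact frame; the translation
    error is the mean displacement of the fragment's own points under it
    (lever-arm aware, unlike a bare ‖Δt‖).
    """
    out: dict[str, tuple[float, float]] = {}
    s_ref_inv = truth.poses[ref_id].inverse()
    for fid, est in result.poses.items():
        if fid not in truth.poses:
            continue
        err = s_ref_inv.compose(est).compose(truth.poses[fid])  # intact -> intact
        cos = np.clip((np.trace(err.rotation) - 1.0) / 2.0, -1.0, 1.0)
        angle = float(np.degrees(np.arccos(cos)))
        pts = truth.poses[fid].inverse().apply(fragments[fid].points)
        trans = float(np.linalg.norm(err.apply(pts) - pts, axis=1).mean())
        out[fid] = (angle, trans)
    return out


def voxelize(
    bone: trimesh.Trimesh,
    spacing: float = 0.5,
    hu_bone: float = 1500.0,
    hu_soft: float = 40.0,
    hu_air: float = -1000.0,
    soft_shell: float = 0.0,
    seed: int = 0,
    noise_frac: float = 0.03,
) -> CtVolume:
    """Solid-interior voxelization of a (closed) mesh into a CT-like volume.

    Bone voxels get ``hu_bone`` with seeded multiplicative noise of
    ``noise_frac`` RMS; an optional soft-tissue shell of the given
    thickness (mm) surrounds the bone at ``hu_soft``; everything else is
    ``hu_air``.  Voxel centre (i, j, k) sits at ``origin + index·spacing``.
    """
    from scipy import ndimage

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    inside = _inside_fn(bone)
    margin = spacing * 2 + soft_shell
    lo = bone.bounds[0] - margin
    hi = bone.bounds[1] + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    provenance = {"spacing_mm": spacing, "soft_shell_mm": soft_shell, "seed": seed}
    min_feature = float(min(bone.extents))
    if spacing > min_feature:
        provenance["warning"] = (
            f"spacing {spacing} mm exceeds thinnest feature {min_feature:.2f} mm"
        )
    ax = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    bone_mask = inside(pts).reshape(tuple(shape))
    vox = np.full(tuple(shape), hu_air, dtype=float)
    if soft_shell > 0:
        it = max(1, int(round(soft_shell / spacing)))
        shell = ndimage.binary_dilation(bone_mask, iterations=it) & ~bone_mask
        vox[shell] = hu_soft
    nb = int(bone_mask.sum())
    vox[bone_mask] = hu_bone * (1.0 + noise_frac * rng.standard_normal(nb))
    return CtVolume(voxels=vox, spacing=np.full(3, float(spacing)), origin=lo, provenance=provenance)
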