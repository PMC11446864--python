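"""Core geometric types and operations.

Everything downstream works on three containers: triangle meshes
(``trimesh.Trimesh``, coordinates in mm), :class:`PointCloud` (the working
representation of every fragment — typically a fixed-size subsample of a
mesh surface), and :class:`RigidTransform` (proper rotation + translation,
the currency passed from fracture-surface registration to whole fragments).

All coordinates are millimetres throughout the package.  Mesh files carry
no unit information; mm is assumed and recorded in metadata.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "RigidTransform",
    "load_mesh",
    "save_mesh",
    "subsample",
    "apply_transform",
    "nearest_distances",
    "load_cloud_ply",
    "save_cloud_ply",
]

#: tolerance (mm) within which duplicate mesh vertices are merged on load
VERTEX_MERGE_TOL = 1e-6

#: tolerance on |det(R) - 1| and orthonormality for a valid rotation
ROTATION_TOL = 1e-9


class MeshFormatError(ValueError):
    """Raised for unreadable, truncated or empty mesh files."""


@dataclasses.dataclass
class PointCloud:
    """N points in 3-D (mm) with an optional per-point scalar field.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of coordinates in mm.
    scalar
        Optional per-point real value (roughness, distance, ...).  NaN
        entries mark points for which the value is undefined.
    parent_index
        Optional per-point index into a source cloud or mesh, used to
        transfer transforms computed on a subset back to its parent.
    """

    points: np.ndarray
    scalar: Optional[np.ndarray] = None
    parent_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        n = len(self.points)
        if self.scalar is not None:
            self.scalar = np.asarray(self.scalar, dtype=float)
            if self.scalar.shape != (n,):
                raise ValueError("scalar must have one value per point")
        if self.parent_index is not None:
            self.parent_index = np.asarray(self.parent_index, dtype=np.intp)
            if self.parent_index.shape != (n,):
                raise ValueError("parent_index must have one entry per point")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_index: np.ndarray) -> "PointCloud":
        """Subset of the cloud; scalar and parent_index are carried along."""
        idx = np.asarray(mask_or_index)
        return PointCloud(
            self.points[idx],
            None if self.scalar is None else self.scalar[idx],
            None if self.parent_index is None else self.parent_index[idx],
        )

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            None if self.scalar is None else self.scalar.copy(),
            None if self.parent_index is None else self.parent_index.copy(),
        )


def concatenate(clouds: list[PointCloud]) -> PointCloud:
    """Concatenate clouds; optional fields survive only if present on all."""
    pts = np.vstack([c.points for c in clouds])
    scalar = None
    if all(c.scalar is not None for c in clouds):
        scalar = np.concatenate([c.scalar for c in clouds])
    return PointCloud(pts, scalar, None)


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion  p -> R p + t  (rotation in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if (
            np.abs(R.T @ R - np.eye(3)).max() > ROTATION_TOL
            or abs(np.linalg.det(R) - 1.0) > ROTATION_TOL
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return RigidTransform(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an STL (binary or ASCII) or PLY mesh, merging duplicate vertices.

    Coordinates are taken in the file's native units and assumed to be mm
    (recorded under ``mesh.metadata['units']``).

    Raises
    ------
    MeshFormatError
        If the file is missing, unreadable/truncated, or contains no
        geometry.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # trimesh raises assorted types for bad bytes
        size = path.stat().st_size
        raise MeshFormatError(
            f"could not parse {path} ({size} bytes): {exc}"
        ) from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle geometry")
    mesh.merge_vertices(digits_vertex=int(round(-np.log10(VERTEX_MERGE_TOL))))
    mesh.metadata["units"] = "mm"
    mesh.metadata["source_file"] = str(path)
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as binary STL (``.stl``) or PLY (``.ply``).

    Refuses to write an empty mesh (and creates no file in that case).
    """
    if mesh is None or len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    mesh.export(str(path))


def _area_weighted_sample(mesh: trimesh.Trimesh, n: int, rng: np.random.Generator) -> np.ndarray:
    areas = mesh.area_faces
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area; cannot sample")
    face_idx = rng.choice(len(areas), size=n, p=areas / total)
    tri = mesh.triangles[face_idx]
    # uniform barycentric coordinates via the square-root trick
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a = 1.0 - r1
    b = r1 * (1.0 - r2)
    c = r1 * r2
    return a[:, None] * tri[:, 0] + b[:, None] * tri[:, 1] + c[:, None] * tri[:, 2]


def _poisson_thin(points: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy Poisson-disk-style thinning to approximately uniform density.

    Accepts points in random order, rejecting any candidate closer than the
    target radius to an already accepted point; the radius targets n points
    on the sampled area.  Returns indices of accepted points (may be < n).
    """
    # hexagonal-packing estimate of the spacing that yields ~n points
    bbox = points.max(axis=0) - points.min(axis=0)
    area_proxy = np.prod(np.sort(bbox)[-2:])  # crude but only sets the scale
    radius = 0.7 * np.sqrt(area_proxy / max(n, 1))
    order = rng.permutation(len(points))
    tree = cKDTree(points)
    accepted: list[int] = []
    blocked = np.zeros(len(points), dtype=bool)
    for i in order:
        if blocked[i]:
            continue
        accepted.append(i)
        if len(accepted) == n:
            break
        blocked[tree.query_ball_point(points[i], radius)] = True
    return np.array(accepted, dtype=np.intp)


def subsample(
    mesh: trimesh.Trimesh,
    n: int = 100_000,
    seed: int = 0,
    mode: str = "random_area_weighted",
) -> PointCloud:
    """Sample exactly ``n`` points on a mesh surface, deterministically.

    The working protocol reduces every fragment mesh to a fixed-size point
    cloud (100 000 points by default) before roughness analysis and
    registration.

    Parameters
    ----------
    mode
        ``random_area_weighted`` draws triangles with probability
        proportional to area, then a uniform barycentric point — density
        follows the tessellation area exactly.  ``homogeneous`` applies
        Poisson-disk-style rejection to an oversampled set, targeting
        spatially uniform density, then tops up randomly to exactly ``n``.
        The mode used is a protocol choice and should be reported with
        results.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if mode == "random_area_weighted":
        return PointCloud(_area_weighted_sample(mesh, n, rng))
    if mode == "homogeneous":
        over = _area_weighted_sample(mesh, max(4 * n, 64), rng)
        keep = _poisson_thin(over, n, rng)
        if len(keep) < n:
            rest = np.setdiff1d(np.arange(len(over)), keep)
            extra = rng.choice(rest, size=n - len(keep), replace=False)
            keep = np.concatenate([keep, extra])
        return PointCloud(over[keep[:n]])
    raise ValueError(f"unknown subsample mode: {mode!r}")


def apply_transform(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Apply a rigid transform to every point; scalar/parent_index carried."""
    return PointCloud(
        transform.apply(cloud.points),
        None if cloud.scalar is None else cloud.scalar.copy(),
        None if cloud.parent_index is None else cloud.parent_index.copy(),
    )


def nearest_distances(query: PointCloud, reference: PointCloud) -> np.ndarray:
    """Euclidean distance from each query point to its nearest reference point.

    This is the cloud-to-cloud distance underlying both the trimmed-ICP
    correspondence step and the reconstruction-accuracy evaluation.
    """
    if len(reference) == 0:
        raise ValueError("reference cloud is empty")
    if len(query) == 0:
        raise ValueError("query cloud is empty")
    tree = cKDTree(reference.points)
    d, _ = tree.query(query.points, workers=-1)
    return d


# ---------------------------------------------------------------------------
# point-cloud PLY with an optional per-vertex scalar
# ---------------------------------------------------------------------------

def save_cloud_ply(cloud: PointCloud, path: str | Path, scalar_name: str = "scalar") -> None:
    """Write a point cloud as ASCII PLY, with the scalar as a vertex property."""
    path = Path(path)
    has_scalar = cloud.scalar is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if has_scalar:
            fh.write(f"property double {scalar_name}\n")
        fh.write("end_header\n")
        cols = [cloud.points]
        if has_scalar:
            cols.append(cloud.scalar[:, None])
        np.savetxt(fh, np.hstack(cols), fmt="%.17g")


def load_cloud_ply(path: str | Path) -> PointCloud:
    """Read an ASCII point-cloud PLY written by :func:`save_cloud_ply`."""
    path = Path(path)
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise MeshFormatError(f"{path}: not a PLY file")
        n_vertex = None
        props: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError(f"{path}: truncated header")
            line = line.strip()
            if line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith("property") and n_vertex is not None:
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        data = np.loadtxt(fh, ndmin=2)
    if n_vertex is None or data.shape[0] != n_vertex:
        raise MeshFormatError(f"{path}: vertex count mismatch")
    scalar = data[:, 3] if len(props) > 3 else None
    return PointCloud(data[:, :3], scalar)
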