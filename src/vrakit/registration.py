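"""Pairwise fragment registration and iterative whole-bone reassembly.

The re-association protocol is two-stage.  An operator declares which
fragments match and marks at least three corresponding landmark points on
the two fracture surfaces; a closed-form least-squares rigid fit to those
correspondences gives the coarse alignment.  Trimmed iterative-closest-point
(ICP) on the two *fracture surfaces only* then refines the pose: each
iteration pairs every moving point with its nearest reference point,
discards pairs beyond a distance gate and the largest-distance tail (the
trimming that makes the fit robust to the non-overlapping parts of the
faces), and re-solves the rigid fit on the kept pairs.  The refined
transform is finally applied to the *full* moving fragment, the clouds are
merged, and the merged model becomes the reference for the next fragment.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform, apply_transform, concatenate
from .roughness import FractureSurface

__all__ = [
    "IcpParams",
    "IcpResult",
    "MatchStep",
    "MatchPlan",
    "ReassemblyResult",
    "rigid_from_correspondences",
    "icp_refine",
    "reassociate_pair",
    "reassemble",
]


class RegistrationError(RuntimeError):
    """Raised when a registration step cannot produce a transform."""


@dataclasses.dataclass
class IcpParams:
    """Tunable parameters of the trimmed-ICP refinement.

    max_corr_dist
        Correspondence distance gate in mm.  The coarse alignment is
        assumed to bring matching surfaces within a few mm, so pairs
        farther than this are treated as non-overlap and ignored.
    trim_keep_fraction
        Fraction of gated correspondences kept each iteration, best-first
        by distance — the "most distant points excluded" rule.
    rel_tol
        Convergence: stop when the relative change of the trimmed RMS
        between iterations falls below this.
    """

    max_iter: int = 50
    rel_tol: float = 1e-6
    trim_keep_fraction: float = 0.8
    max_corr_dist: float = 5.0
    #: optional second refinement pass with this tighter correspondence
    #: gate, run from the first pass's best pose: once the surfaces are
    #: roughly mated, far points (rim cortex, unrelated faces) carry only
    #: bias, and a close-pairs-only pass removes the residual tilt
    polish_gate: Optional[float] = None
    #: minimise point-to-plane instead of point-to-point distances
    #: (normals from local PCA of the reference surface).  Point-to-point
    #: correspondences cannot observe the tilt of a nearly planar face at
    #: finite sampling density; the plane metric restores it
    point_to_plane: bool = False
    #: use the point-to-plane metric during the polish pass (ignored when
    #: ``polish_gate`` is unset)
    polish_point_to_plane: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.trim_keep_fraction <= 1.0):
            raise ValueError("trim_keep_fraction must be in (0, 1]")
        if self.max_iter < 1 or self.rel_tol < 0 or self.max_corr_dist <= 0:
            raise ValueError("invalid ICP parameters")


@dataclasses.dataclass
class IcpResult:
    """Outcome of one trimmed-ICP run (composed with its initialisation)."""

    transform: RigidTransform
    final_rms: float
    iterations: int
    converged: bool
    kept_fraction: float
    rms_history: list[float] = dataclasses.field(default_factory=list)


def rigid_from_correspondences(ref_points: np.ndarray, mov_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``mov`` onto ``ref``.

    Solves  argmin_{R,t} Σ ||R·mov_i + t − ref_i||²  in closed form via the
    SVD of the cross-covariance matrix, with the determinant correction
    that excludes reflections.

    Raises
    ------
    RegistrationError
        For fewer than 3 pairs or a collinear/degenerate configuration
        (cross-covariance rank < 2), where the rotation is not determined.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(mov_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref_points and mov_points must be matching (N, 3) arrays")
    if len(ref) < 3:
        raise RegistrationError(f"need >= 3 correspondences, got {len(ref)}")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    scale = max(np.linalg.norm(ref - ref_c, axis=1).max(), 1e-300)
    if s[1] <= 1e-9 * scale**2:
        raise RegistrationError("degenerate correspondence configuration (collinear points)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # re-orthonormalise to keep the SO(3) invariant at machine precision
    uu, _, vv = np.linalg.svd(rot)
    rot = uu @ vv
    t = ref_c - rot @ mov_c
    return RigidTransform(rot, t)


def _surface_normals(points: np.ndarray, tree: cKDTree, k: int = 10) -> np.ndarray:
    """Unit normals from local PCA over the k nearest neighbours."""
    _, idx = tree.query(points, k=min(k, len(points)), workers=-1)
    nbr = points[idx]  # (N, k, 3)
    centred = nbr - nbr.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred)
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, :, 0]


def _solve_point_to_plane(
    moved: np.ndarray, ref: np.ndarray, normals: np.ndarray
) -> RigidTransform:
    """One linearised point-to-plane step: small rotation + translation
    minimising Σ ((R·p + t − q)·n)²."""
    c = np.cross(moved, normals)
    a = np.hstack([c, normals])  # (N, 6) rows [p×n, n]
    b = -np.einsum("ij,ij->i", moved - ref, normals)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    w, t = x[:3], x[3:]
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        rot = np.eye(3)
    else:
        k = w / theta
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
    u, _, vt = np.linalg.svd(rot)
    return RigidTransform(u @ vt, t)


def icp_refine(
    ref: PointCloud,
    mov: PointCloud,
    init: Optional[RigidTransform] = None,
    params: Optional[IcpParams] = None,
) -> IcpResult:
    """Trimmed point-to-point ICP of ``mov`` onto ``ref``.

    Returns the *composed* transform (including ``init``) that maps the
    original moving cloud onto the reference.  The trimmed RMS over the
    kept correspondences is tracked per iteration; the update re-solves
    the rigid fit on the kept pairs, which cannot increase the trimmed
    objective, so the history is non-increasing up to the distance gate.
    """
    if params is None:
        params = IcpParams()
    if init is None:
        init = RigidTransform.identity()
    if len(ref) == 0 or len(mov) == 0:
        raise RegistrationError("empty cloud passed to ICP")
    if params.polish_gate is not None:
        first = icp_refine(
            ref, mov, init, dataclasses.replace(params, polish_gate=None)
        )
        polish_params = dataclasses.replace(
            params,
            polish_gate=None,
            max_corr_dist=params.polish_gate,
            point_to_plane=params.point_to_plane or params.polish_point_to_plane,
        )
        try:
            second = icp_refine(ref, mov, first.transform, polish_params)
        except RegistrationError:
            return first
        second.rms_history = first.rms_history + second.rms_history
        second.iterations += first.iterations
        return second
    tree = cKDTree(ref.points)
    normals = _surface_normals(ref.points, tree) if params.point_to_plane else None
    transform = init
    history: list[float] = []
    best_rms = np.inf
    best_transform = init
    best_kept = 0.0
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        moved = transform.apply(mov.points)
        dist, idx = tree.query(moved, workers=-1)
        gate = dist <= params.max_corr_dist
        if not np.any(gate):
            raise RegistrationError(
                "no correspondences within max_corr_dist="
                f"{params.max_corr_dist} mm (min distance {dist.min():.3f} mm, "
                f"{len(mov)} moving points)"
            )
        gated = np.where(gate)[0]
        n_keep = max(3, int(np.ceil(params.trim_keep_fraction * len(gated))))
        n_keep = min(n_keep, len(gated))
        keep = gated[np.argsort(dist[gated], kind="stable")[:n_keep]]
        if normals is not None:
            resid = np.einsum(
                "ij,ij->i", moved[keep] - ref.points[idx[keep]], normals[idx[keep]]
            )
            rms = float(np.sqrt(np.mean(resid**2)))
        else:
            rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(rms)
        if rms < best_rms:
            # the distance gate can reshuffle the kept set between
            # iterations, so the trimmed RMS is not guaranteed monotone;
            # keep the best pose seen rather than the last
            best_rms = rms
            best_transform = transform
            best_kept = n_keep / len(mov)
        if rms <= 1e-12 or (
            len(history) >= 2
            and abs(history[-2] - rms) <= params.rel_tol * max(rms, 1e-300)
        ):
            converged = True
            break
        try:
            if normals is not None:
                delta = _solve_point_to_plane(
                    moved[keep], ref.points[idx[keep]], normals[idx[keep]]
                )
                transform = delta.compose(transform)
            else:
                transform = rigid_from_correspondences(
                    ref.points[idx[keep]], mov.points[keep]
                )
        except (RegistrationError, np.linalg.LinAlgError):
            # kept pairs degenerate (e.g. tiny overlap collapsed to a line)
            break
    return IcpResult(
        transform=best_transform,
        final_rms=best_rms,
        iterations=iterations,
        converged=converged,
        kept_fraction=best_kept,
        rms_history=history,
    )


# ---------------------------------------------------------------------------
# match plans
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MatchStep:
    """One operator-declared candidate pair with landmark correspondences.

    ``ref_points``/``mov_points`` are >= 3 corresponding landmark
    coordinates (mm) in the current frames of the two fragments.
    ``surface_radius``, when set, restricts the ICP refinement to
    fracture points within that distance (mm) of the clicked landmarks —
    the operator's selection of *which* broken faces are being matched.
    """

    ref_id: str
    mov_id: str
    ref_points: np.ndarray
    mov_points: np.ndarray
    icp_overrides: dict = dataclasses.field(default_factory=dict)
    surface_radius: Optional[float] = None
    #: half-thickness (mm) of a slab around the landmarks' best-fit plane;
    #: fracture points outside it are excluded from the refinement (the
    #: face being matched is roughly planar, other faces of the same
    #: fragment are not coplanar with it)
    surface_band: Optional[float] = None

    def __post_init__(self) -> None:
        self.ref_points = np.asarray(self.ref_points, dtype=float).reshape(-1, 3)
        self.mov_points = np.asarray(self.mov_points, dtype=float).reshape(-1, 3)
        if len(self.ref_points) < 3 or len(self.ref_points) != len(self.mov_points):
            raise ValueError(
                f"step {self.ref_id}->{self.mov_id}: need >= 3 correspondence pairs"
            )


@dataclasses.dataclass
class MatchPlan:
    """Ordered sequence of match steps; order defines the accumulation."""

    steps: list[MatchStep]

    def __len__(self) -> int:
        return len(self.steps)

    @staticmethod
    def from_file(path: str | Path) -> "MatchPlan":
        """Read a plan from YAML or JSON (list of step mappings)."""
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        steps = [
            MatchStep(
                ref_id=str(s["ref_id"]),
                mov_id=str(s["mov_id"]),
                ref_points=s["ref_points"],
                mov_points=s["mov_points"],
                icp_overrides=s.get("icp", {}),
                surface_radius=s.get("surface_radius"),
                surface_band=s.get("surface_band"),
            )
            for s in doc["steps"]
        ]
        return MatchPlan(steps)

    def to_file(self, path: str | Path) -> None:
        doc = {
            "steps": [
                {
                    "ref_id": s.ref_id,
                    "mov_id": s.mov_id,
                    "ref_points": s.ref_points.tolist(),
                    "mov_points": s.mov_points.tolist(),
                    **({"icp": s.icp_overrides} if s.icp_overrides else {}),
                    **(
                        {"surface_radius": s.surface_radius}
                        if s.surface_radius is not None
                        else {}
                    ),
                    **(
                        {"surface_band": s.surface_band}
                        if s.surface_band is not None
                        else {}
                    ),
                }
                for s in self.steps
            ]
        }
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(doc, fh, indent=1)
            else:
                yaml.safe_dump(doc, fh)


def reassociate_pair(
    ref_fragment: PointCloud,
    mov_fragment: PointCloud,
    ref_surface: FractureSurface,
    mov_surface: FractureSurface,
    ref_points: np.ndarray,
    mov_points: np.ndarray,
    params: Optional[IcpParams] = None,
) -> tuple[PointCloud, IcpResult]:
    """Register one moving fragment onto a reference and merge the clouds.

    Coarse alignment from the landmark correspondences, trimmed-ICP
    refinement on the two *fracture surfaces*, then the refined transform
    is applied to the full moving fragment ("the transformation
    coordinates" travel from the fracture-surface fit to the whole
    fragment).  The merged cloud is the plain concatenation of reference
    and transformed moving fragment — no deduplication, so its size is
    exactly ``len(ref_fragment) + len(mov_fragment)``.
    """
    coarse = rigid_from_correspondences(ref_points, mov_points)
    result = icp_refine(ref_surface.cloud, mov_surface.cloud, init=coarse, params=params)
    moved = apply_transform(mov_fragment, result.transform)
    merged = concatenate([ref_fragment, moved])
    return merged, result


@dataclasses.dataclass
class StepRecord:
    """Diagnostics for one reassembly step."""

    ref_id: str
    mov_id: str
    success: bool
    icp: Optional[IcpResult] = None
    error: Optional[str] = None


@dataclasses.dataclass
class ReassemblyResult:
    """Outcome of a sequential reassembly.

    poses
        Final pose per fragment ID: the composed chain of step transforms
        mapping the fragment's input frame into the frame of the assembly
        it ended up in (identity for fragments never moved).
    merged
        One merged cloud per remaining assembly, keyed by the ID of its
        founding (reference) fragment.
    steps
        Per-step diagnostics in plan order, including failures.
    """

    poses: dict[str, RigidTransform]
    merged: dict[str, PointCloud]
    steps: list[StepRecord]
    n_fragments_total: int
    n_attempted: int
    n_reassociated: int

    def pose_manifest(self) -> dict:
        """JSON-ready manifest: poses as 4x4 row-major matrices."""
        return {
            "poses": {k: t.as_matrix().tolist() for k, t in self.poses.items()},
            "steps": [
                {
                    "ref_id": s.ref_id,
                    "mov_id": s.mov_id,
                    "success": s.success,
                    "final_rms": None if s.icp is None else s.icp.final_rms,
                    "iterations": None if s.icp is None else s.icp.iterations,
                    "converged": None if s.icp is None else s.icp.converged,
                    "error": s.error,
                }
                for s in self.steps
            ],
            "n_fragments_total": self.n_fragments_total,
            "n_attempted": self.n_attempted,
            "n_reassociated": self.n_reassociated,
        }


def _select_near(
    cloud: PointCloud,
    landmarks: np.ndarray,
    radius: Optional[float],
    band: Optional[float] = None,
) -> PointCloud:
    """Operator-style surface selection around the clicked landmarks.

    Keeps points within ``radius`` of a landmark and, when ``band`` is
    given and the landmarks span a plane, within ``band`` of the
    landmarks' best-fit plane.  Falls back to the full cloud when the
    selection would be too sparse to register.
    """
    mask = np.ones(len(cloud), dtype=bool)
    if radius is not None:
        d = np.min(
            np.linalg.norm(cloud.points[:, None, :] - landmarks[None, :, :], axis=2),
            axis=1,
        )
        mask &= d <= radius
    if band is not None and len(landmarks) >= 3:
        centre = landmarks.mean(axis=0)
        dl = landmarks - centre
        w, v = np.linalg.eigh(dl.T @ dl)
        if w[1] > 1e-9 * max(w[2], 1e-300):  # landmarks not collinear
            normal = v[:, 0]
            mask &= np.abs((cloud.points - centre) @ normal) <= band
    keep = np.where(mask)[0]
    if len(keep) < 10:
        return cloud
    return cloud.select(keep)


def reassemble(
    fragments: dict[str, PointCloud],
    surfaces: dict[str, FractureSurface],
    plan: MatchPlan,
    params: Optional[IcpParams] = None,
    refine_sweeps: int = 1,
) -> ReassemblyResult:
    """Sequentially re-associate fragments following the plan order.

    After each successful step the merged model becomes the reference for
    subsequent steps that target any fragment already absorbed into it.
    A failed step is recorded and the pipeline continues with the rest of
    the plan — a partial reconstruction is a valid outcome.

    After the last plan step, ``refine_sweeps`` passes re-register each
    placed fragment once against the rest of its assembled model with a
    tight correspondence gate (point-to-plane).  This is the operator's
    final adjustment: a fragment initially placed through one narrow
    face is now braced by *all* the interfaces it shares with the
    assembly, which pins down the tilt a single face leaves weakly
    constrained.  The assembly root stays fixed (it defines the frame).
    """
    if params is None:
        params = IcpParams()
    assembly_of = {fid: fid for fid in fragments}  # fragment -> assembly key

    def root(fid: str) -> str:
        while assembly_of[fid] != fid:
            fid = assembly_of[fid]
        return fid

    clouds = {fid: c.copy() for fid, c in fragments.items()}
    # fracture surfaces are kept per fragment: each step refines against
    # the mated face of the reference fragment (the operator's selected
    # matching surface); the refinement sweep afterwards braces every
    # fragment against all its interfaces in the assembled model
    frac = {fid: s.cloud.copy() for fid, s in surfaces.items()}
    members: dict[str, list[str]] = {fid: [fid] for fid in fragments}
    poses = {fid: RigidTransform.identity() for fid in fragments}
    records: list[StepRecord] = []
    n_ok = 0
    for step in plan.steps:
        if step.ref_id not in fragments or step.mov_id not in fragments:
            records.append(
                StepRecord(step.ref_id, step.mov_id, False, error="unknown fragment id")
            )
            continue
        ra, rb = root(step.ref_id), root(step.mov_id)
        if ra == rb:
            records.append(
                StepRecord(step.ref_id, step.mov_id, False, error="already in same assembly")
            )
            continue
        step_params = dataclasses.replace(params, **step.icp_overrides)
        # landmarks were picked in the fragments' input frames; bring them
        # into the current assembly frames
        ref_pts = poses[step.ref_id].apply(step.ref_points)
        mov_pts = poses[step.mov_id].apply(step.mov_points)
        ref_surf = apply_transform(frac[step.ref_id], poses[step.ref_id])
        mov_surf = apply_transform(frac[step.mov_id], poses[step.mov_id])
        if step.surface_radius is not None or step.surface_band is not None:
            ref_surf = _select_near(ref_surf, ref_pts, step.surface_radius, step.surface_band)
            mov_surf = _select_near(mov_surf, mov_pts, step.surface_radius, step.surface_band)
        try:
            coarse = rigid_from_correspondences(ref_pts, mov_pts)
            icp = icp_refine(ref_surf, mov_surf, init=coarse, params=step_params)
        except RegistrationError as exc:
            records.append(StepRecord(step.ref_id, step.mov_id, False, error=str(exc)))
            continue
        # the refinement ran on clouds already in the assemblies' current
        # frames, so its transform applies directly to the moving assembly
        t = icp.transform
        clouds[ra] = concatenate([clouds[ra], apply_transform(clouds[rb], t)])
        for fid in members[rb]:
            poses[fid] = t.compose(poses[fid])
        members[ra].extend(members[rb])
        assembly_of[rb] = ra
        del clouds[rb], members[rb]
        records.append(StepRecord(step.ref_id, step.mov_id, True, icp=icp))
        n_ok += 1

    sweep_params = IcpParams(
        max_corr_dist=1.0,
        trim_keep_fraction=0.8,
        point_to_plane=True,
        max_iter=30,
    )
    placement_order = [r.mov_id for r in records if r.success]
    for _ in range(max(0, refine_sweeps)):
        for fid in placement_order:
            rid = root(fid)
            others = [g for g in members[rid] if g != fid]
            if not others:
                continue
            mov_surf = apply_transform(frac[fid], poses[fid])
            lo = mov_surf.points.min(axis=0) - 2 * sweep_params.max_corr_dist
            hi = mov_surf.points.max(axis=0) + 2 * sweep_params.max_corr_dist
            parts = []
            for g in others:
                placed = apply_transform(frac[g], poses[g])
                box = np.all((placed.points >= lo) & (placed.points <= hi), axis=1)
                if box.any():
                    parts.append(placed.select(np.where(box)[0]))
            if not parts:
                continue
            ref_surf = concatenate(parts)
            try:
                touch = icp_refine(ref_surf, mov_surf, params=sweep_params)
            except RegistrationError:
                continue
            poses[fid] = touch.transform.compose(poses[fid])
    if refine_sweeps > 0 and n_ok:
        # rebuild the merged clouds from the refined poses
        for rid in list(clouds):
            clouds[rid] = concatenate(
                [apply_transform(fragments[g], poses[g]) for g in members[rid]]
            )

    return ReassemblyResult(
        poses=poses,
        merged=clouds,
        steps=records,
        n_fragments_total=len(fragments),
        n_attempted=len(plan),
        n_reassociated=n_ok,
    )
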