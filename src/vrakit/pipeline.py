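"""Config-driven orchestration of the full re-association workflow.

A single YAML/JSON config document drives any subset of the stages

    simulate -> segment -> roughness -> match -> reassemble -> evaluate -> stats

in that fixed order.  Every stage writes its artefacts plus a provenance
record (parameters, seeds, package version) into the output directory, and
re-running with an identical config is bit-reproducible for the
deterministic stages.  All random seeds are mandatory fields of the
config — there are no silent defaults for randomness.

The in-memory state produced by earlier stages is passed along; stages are
self-contained enough that a later run can resume from the artefacts of a
previous one where that makes sense (the CLI exposes the same stages as
subcommands for piecemeal use).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import yaml

from . import __version__
from .ct import region_grow, save_volume
from .evaluation import (
    register_and_compare,
    round_half_up,
    paired_correlation,
    summary_stats,
)
from .geometry import PointCloud, apply_transform, save_cloud_ply
from .registration import IcpParams, reassemble
from .roughness import (
    DEFAULT_KERNEL_RADIUS,
    DEFAULT_THRESHOLD,
    FractureSurface,
    roughness,
    segment_fracture,
)
from .synthetic import (
    build_match_plan,
    fracture,
    make_long_bone,
    pose_recovery_errors,
    voxelize,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "segment", "roughness", "match", "reassemble", "evaluate", "stats")


class ConfigError(ValueError):
    """Raised when a pipeline config fails validation, before any work."""


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``bones`` is a list of per-specimen dicts; each must carry its own
    ``n_fragments`` (or one is drawn at study scale from the seed).
    """

    seed: int
    output_dir: Path
    stages: list[str]
    bones: list[dict]
    bone_params: dict = dataclasses.field(default_factory=dict)
    fracture_params: dict = dataclasses.field(default_factory=dict)
    icp: dict = dataclasses.field(default_factory=dict)
    roughness_kernel_mm: float = DEFAULT_KERNEL_RADIUS
    roughness_threshold: float = DEFAULT_THRESHOLD
    landmark_sigma_mm: float = 0.25
    refine_sweeps: int = 2
    segment_spacing_mm: float = 1.0
    write_artifacts: bool = True

    @staticmethod
    def from_dict(doc: dict) -> "PipelineConfig":
        missing = [k for k in ("seed", "output_dir", "stages") if k not in doc]
        if missing:
            raise ConfigError(f"config missing required keys: {missing}")
        stages = list(doc["stages"])
        if not stages:
            raise ConfigError("stages list is empty")
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}; valid: {list(STAGES)}")
        bones = doc.get("bones")
        if not bones:
            raise ConfigError("config must declare at least one bone under 'bones'")
        for i, b in enumerate(bones):
            if "seed" not in b:
                raise ConfigError(f"bones[{i}] missing mandatory per-bone 'seed'")
        return PipelineConfig(
            seed=int(doc["seed"]),
            output_dir=Path(doc["output_dir"]),
            stages=stages,
            bones=[dict(b) for b in bones],
            bone_params=dict(doc.get("bone_params", {})),
            fracture_params=dict(doc.get("fracture_params", {})),
            icp=dict(doc.get("icp", {})),
            roughness_kernel_mm=float(doc.get("roughness_kernel_mm", DEFAULT_KERNEL_RADIUS)),
            roughness_threshold=float(doc.get("roughness_threshold", DEFAULT_THRESHOLD)),
            landmark_sigma_mm=float(doc.get("landmark_sigma_mm", 0.25)),
            refine_sweeps=int(doc.get("refine_sweeps", 2)),
            segment_spacing_mm=float(doc.get("segment_spacing_mm", 1.0)),
            write_artifacts=bool(doc.get("write_artifacts", True)),
        )

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh))


def _provenance(stage: str, cfg: PipelineConfig, extra: dict) -> dict:
    return {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        **extra,
    }


def _write_json(path: Path, doc: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the configured stages; returns the final state dictionary.

    The state maps bone IDs to their fragments, surfaces, plans, results
    and metrics as stages complete.  Stage failures are recorded under
    ``state['failures']`` and later independent stages continue.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_file(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {"bones": {}, "failures": [], "output_dir": out}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        try:
            _STAGE_FUNCS[stage](cfg, state)
        except Exception as exc:  # record, continue with later stages
            state["failures"].append({"stage": stage, "error": str(exc)})
    return state


def _stage_simulate(cfg: PipelineConfig, state: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    for i, bone_cfg in enumerate(cfg.bones):
        bone_id = bone_cfg.get("id", f"bone{i:02d}")
        bone_seed = int(bone_cfg["seed"])
        params = {**cfg.bone_params, **bone_cfg.get("bone_params", {})}
        mesh = make_long_bone(seed=bone_seed, **params)
        n_frag = bone_cfg.get("n_fragments")
        if n_frag is None:
            from .synthetic import default_fragment_count

            n_frag = default_fragment_count(rng)
        fragments, truth = fracture(
            mesh, int(n_frag), seed=bone_seed, **cfg.fracture_params
        )
        state["bones"][bone_id] = {
            "mesh": mesh,
            "fragments": fragments,
            "truth": truth,
        }
        if cfg.write_artifacts:
            bdir = cfg.output_dir / bone_id
            bdir.mkdir(parents=True, exist_ok=True)
            for fid, cloud in fragments.items():
                save_cloud_ply(cloud, bdir / f"{fid}.ply")
            save_cloud_ply(truth.intact, bdir / "intact.ply")
            _write_json(
                bdir / "truth.json",
                {
                    "poses": {k: t.as_matrix().tolist() for k, t in truth.poses.items()},
                    "lost": truth.lost,
                    "adjacency": truth.adjacency,
                    "params": truth.params,
                    "seed": truth.seed,
                },
            )
    _write_json(
        cfg.output_dir / "simulate.provenance.json",
        _provenance("simulate", cfg, {"n_bones": len(cfg.bones)}),
    )


def _stage_segment(cfg: PipelineConfig, state: dict) -> None:
    """Voxelize each intact bone and segment it back out (CT round-trip).

    A self-check stage: the recovered voxel count per bone is recorded so
    segmentation bias is visible in provenance.
    """
    report = {}
    for bone_id, entry in state["bones"].items():
        mesh = entry["mesh"]
        vol = voxelize(mesh, spacing=cfg.segment_spacing_mm, seed=cfg.seed)
        seed_idx = tuple(int(c) for c in np.unravel_index(np.argmax(vol.voxels), vol.voxels.shape))
        mask = region_grow(vol, [seed_idx])
        entry["volume"] = vol
        entry["mask"] = mask
        report[bone_id] = {
            "bone_voxels": int((mask.labels > 0).sum()),
            "spacing_mm": cfg.segment_spacing_mm,
        }
        if cfg.write_artifacts:
            save_volume(vol, cfg.output_dir / bone_id / "volume.nrrd")
    _write_json(
        cfg.output_dir / "segment.provenance.json", _provenance("segment", cfg, report)
    )


def _stage_roughness(cfg: PipelineConfig, state: dict) -> None:
    for bone_id, entry in state["bones"].items():
        surfaces: dict[str, FractureSurface] = {}
        clouds_r: dict[str, PointCloud] = {}
        for fid, cloud in entry["fragments"].items():
            with_r = roughness(cloud, kernel_radius=cfg.roughness_kernel_mm)
            clouds_r[fid] = with_r
            surfaces[fid] = segment_fracture(with_r, threshold=cfg.roughness_threshold)
            if cfg.write_artifacts:
                save_cloud_ply(
                    with_r, cfg.output_dir / bone_id / f"{fid}.roughness.ply", "roughness"
                )
        entry["roughness"] = clouds_r
        entry["surfaces"] = surfaces
    _write_json(
        cfg.output_dir / "roughness.provenance.json",
        _provenance(
            "roughness",
            cfg,
            {"kernel_mm": cfg.roughness_kernel_mm, "threshold": cfg.roughness_threshold},
        ),
    )


def _stage_match(cfg: PipelineConfig, state: dict) -> None:
    for bone_id, entry in state["bones"].items():
        plan = build_match_plan(
            entry["fragments"],
            entry["truth"],
            seed=cfg.seed,
            landmark_sigma=cfg.landmark_sigma_mm,
        )
        entry["plan"] = plan
        if cfg.write_artifacts:
            plan.to_file(cfg.output_dir / bone_id / "plan.yaml")
    _write_json(
        cfg.output_dir / "match.provenance.json",
        _provenance("match", cfg, {"landmark_sigma_mm": cfg.landmark_sigma_mm}),
    )


def _stage_reassemble(cfg: PipelineConfig, state: dict) -> None:
    params = IcpParams(**cfg.icp) if cfg.icp else IcpParams()
    for bone_id, entry in state["bones"].items():
        result = reassemble(
            entry["fragments"],
            entry["surfaces"],
            entry["plan"],
            params,
            refine_sweeps=cfg.refine_sweeps,
        )
        entry["result"] = result
        if cfg.write_artifacts:
            _write_json(cfg.output_dir / bone_id / "reassembly.json", result.pose_manifest())
            for root_id, cloud in result.merged.items():
                save_cloud_ply(cloud, cfg.output_dir / bone_id / f"merged.{root_id}.ply")
    _write_json(
        cfg.output_dir / "reassemble.provenance.json",
        _provenance("reassemble", cfg, {"icp": dataclasses.asdict(params)}),
    )


def _stage_evaluate(cfg: PipelineConfig, state: dict) -> None:
    for bone_id, entry in state["bones"].items():
        result = entry["result"]
        truth = entry["truth"]
        ref_id = max(result.merged, key=lambda k: len(result.merged[k]))
        # the reconstructed *exterior* surface is what gets compared with
        # the intact bone, as a surface scan of a physically reassembled
        # bone sees only the outside: cortical-labelled points only
        parts = [
            result.poses[fid].apply(entry["fragments"][fid].points[~truth.fracture_mask[fid]])
            for fid in result.poses
            if fid in entry["fragments"]
        ]
        merged = PointCloud(np.vstack(parts))
        # gauge fix: bring the assembly from the reference fragment's
        # delivered frame back to the intact frame before registration
        aligned = apply_transform(merged, truth.poses[ref_id].inverse())
        distances, metrics = register_and_compare(
            aligned,
            truth.intact,
            n_fragments_total=result.n_fragments_total,
            n_reassociated=result.n_reassociated,
        )
        errors = pose_recovery_errors(result, truth, entry["fragments"], ref_id)
        entry["metrics"] = metrics
        entry["pose_errors"] = errors
        if cfg.write_artifacts:
            field = PointCloud(aligned.points, distances)
            save_cloud_ply(field, cfg.output_dir / bone_id / "distance_field.ply", "distance")
            _write_json(
                cfg.output_dir / bone_id / "metrics.json",
                {
                    "mean_distance_mm": metrics.mean_distance,
                    "rms_distance_mm": metrics.rms_distance,
                    "coverage": metrics.coverage,
                    "n_fragments_total": metrics.n_fragments_total,
                    "n_reassociated": metrics.n_reassociated,
                    "pose_errors": {
                        k: {"rotation_deg": a, "translation_mm": t}
                        for k, (a, t) in errors.items()
                    },
                },
            )
    _write_json(
        cfg.output_dir / "evaluate.provenance.json", _provenance("evaluate", cfg, {})
    )


def _stage_stats(cfg: PipelineConfig, state: dict) -> None:
    bones = state["bones"]
    if not bones:
        raise RuntimeError("stats stage requires evaluated bones")
    means = [e["metrics"].mean_distance for e in bones.values()]
    covs = [e["metrics"].coverage for e in bones.values()]
    counts = [e["metrics"].n_fragments_total for e in bones.values()]
    reassoc = [e["metrics"].n_reassociated for e in bones.values()]
    dist_stats = summary_stats(means)
    doc = {
        "n_bones": len(bones),
        "mean_distance_mm": {
            "mean": dist_stats.mean,
            "sd": dist_stats.sd,
            "min": dist_stats.min,
            "max": dist_stats.max,
            "display_mean": round_half_up(dist_stats.mean, 1),
        },
        "coverage_min": min(covs),
        "fragments": dataclasses.asdict(summary_stats(counts)),
        "reassociated": dataclasses.asdict(summary_stats(reassoc)),
    }
    if len(counts) >= 3 and np.std(counts) > 0 and np.std(reassoc) > 0:
        doc["pearson_fragments_vs_reassociated"] = paired_correlation(counts, reassoc)
    state["stats"] = doc
    _write_json(cfg.output_dir / "stats.json", doc)
    _write_json(cfg.output_dir / "stats.provenance.json", _provenance("stats", cfg, {}))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "roughness": _stage_roughness,
    "match": _stage_match,
    "reassemble": _stage_reassemble,
    "evaluate": _stage_evaluate,
    "stats": _stage_stats,
}
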