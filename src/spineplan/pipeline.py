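"""End-to-end experiment orchestration.

``run_demo`` stands in for a full evaluation protocol: build a statistical
shape model from a generated phantom population, then for each held-out
phantom simulate a two-view acquisition (target images plus landmark
detections), initialize and optimize the 21-DoF reconstruction, propagate
both transpedicular paths, verify them against the ground-truth anatomy, and
score the reconstruction. ``run_baseline`` runs the same cases through the
triangulation-only planner (independent 2D endpoint annotations per view,
ray-midpoint triangulation) for a side-by-side comparison on an identical
report schema.

Everything is deterministic under the configured seeds: per-case seeds are
derived from the experiment seed, and reports are written with a fixed
column order, so repeated runs produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .camera import Camera, angular_separation_deg, look_at_camera, project_points
from .mesh import LabeledMesh
from .metrics import evaluate_reconstruction
from .phantom import (DEFAULT_VARIATION, PhantomParams, generate_vertebra, path_axes,
                      sample_params)
from .planning import (PathPlan, PlanningFailure, breach_check, geoplan_triangulate,
                       plan_success, propagate_path)
from .registration import (METRICS, DegenerateGeometryError, InitializationError,
                           OptimizationConfig, default_schedule, initialize_pose,
                           optimize_multiscale)
from .simulate import make_target_views, simulate_detections
from .ssm import ShapeModel, build_ssm_from_meshes

REPORT_COLUMNS = [
    "case_id", "case_seed", "separation_deg", "init_fallback", "n_common_landmarks",
    "initial_loss", "final_loss", "improved",
    "dice", "nsd", "hd95_mm", "masd_mm",
    "left_min_wall_mm", "left_breach", "right_min_wall_mm", "right_breach",
    "success", "failure_reason",
]

FAILURE_REASONS = (
    "initialization-failure", "degenerate-geometry", "non-improved",
    "planning-failure", "breach",
)


@dataclass
class CameraSpec:
    """Two-view acquisition geometry.

    ``mode`` is "orthogonal" (anteroposterior + lateral, zero elevation) or
    "random" (cameras on a sphere about the isocenter: uniform azimuth,
    elevation within ``elevation_limit_deg``, pairwise separation at least
    ``min_separation_deg``).
    """

    mode: str = "orthogonal"
    n_views: int = 2
    min_separation_deg: float = 15.0
    elevation_limit_deg: float = 45.0
    distance_mm: float = 600.0
    focal_px: float = 640.0
    image_size: tuple[int, int] = (128, 128)

    def __post_init__(self):
        if self.mode not in ("orthogonal", "random"):
            raise ValueError("camera mode must be 'orthogonal' or 'random'")
        if self.n_views < 2:
            raise ValueError("need at least two views")
        if not (0.0 < self.min_separation_deg < 180.0):
            raise ValueError("min_separation_deg must be in (0, 180)")


@dataclass
class DetectionNoiseSpec:
    pixel_sd: float = 1.0
    dropout_prob: float = 0.1

    def __post_init__(self):
        if self.pixel_sd < 0 or not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("invalid detection noise spec")


@dataclass
class TargetImageSpec:
    """Inverse-crime mitigation for the simulated target radiographs."""

    sigma_scale: float = 1.5
    speckle_sd: float = 0.05
    read_noise_sd: float = 0.01


@dataclass
class PoseVariationSpec:
    """Random ground-truth patient pose applied to each held-out phantom."""

    max_rotation_deg: float = 15.0
    max_translation_mm: float = 10.0


@dataclass
class PipelineConfig:
    population_size: int = 25
    variation: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VARIATION))
    n_modes: int = 5
    n_cases: int = 10
    cameras: CameraSpec = field(default_factory=CameraSpec)
    detection: DetectionNoiseSpec = field(default_factory=DetectionNoiseSpec)
    target: TargetImageSpec = field(default_factory=TargetImageSpec)
    pose: PoseVariationSpec = field(default_factory=PoseVariationSpec)
    optimizer: OptimizationConfig = field(default_factory=OptimizationConfig)
    metric: str = "ncc-smooth"
    # coarse-to-fine refinement: second optimization pass under lightly
    # smoothed NCC; None disables it (single-scale)
    fine_sigma_px: float | None = 1.0
    fine_iters: int = 200
    voxel_mm: float = 1.0
    seed: int = 0
    out_dir: str | None = None
    verbose: bool = False

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {sorted(METRICS)}")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["optimizer"]["stages"] = [list(s) for s in self.optimizer.stages]
        d["cameras"]["image_size"] = list(self.cameras.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cameras" in d:
            c = dict(d["cameras"])
            if "image_size" in c:
                c["image_size"] = tuple(c["image_size"])
            d["cameras"] = CameraSpec(**c)
        if "detection" in d:
            d["detection"] = DetectionNoiseSpec(**d["detection"])
        if "target" in d:
            d["target"] = TargetImageSpec(**d["target"])
        if "pose" in d:
            d["pose"] = PoseVariationSpec(**d["pose"])
        if "optimizer" in d:
            o = dict(d["optimizer"])
            if "stages" in o:
                o["stages"] = tuple((g, int(n)) for g, n in o["stages"])
            d["optimizer"] = OptimizationConfig(**o)
        return cls(**d)


def make_case_cameras(spec: CameraSpec, center: np.ndarray,
                      rng: np.random.Generator) -> list[Camera]:
    """Sample an acquisition geometry per the camera spec."""
    common = dict(distance_mm=spec.distance_mm, focal_px=spec.focal_px,
                  image_size=spec.image_size)
    if spec.mode == "orthogonal":
        angles = [(0.0, 0.0), (90.0, 0.0)] + [
            (float(rng.uniform(0, 360)), 0.0) for _ in range(spec.n_views - 2)
        ]
        return [look_at_camera(center, az, el, **common) for az, el in angles]

    cams: list[Camera] = []
    attempts = 0
    while len(cams) < spec.n_views:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not satisfy the pairwise-separation constraint")
        az = float(rng.uniform(0.0, 360.0))
        el = float(rng.uniform(-spec.elevation_limit_deg, spec.elevation_limit_deg))
        cam = look_at_camera(center, az, el, **common)
        if all(angular_separation_deg(cam, c) >= spec.min_separation_deg for c in cams):
            cams.append(cam)
    return cams


@dataclass
class Case:
    """One held-out phantom with its ground-truth pose and acquisition."""

    case_id: int
    case_seed: int
    params: PhantomParams
    truth_mesh: LabeledMesh  # in world (posed) coordinates
    pose_R: np.ndarray
    pose_t: np.ndarray
    cameras: list[Camera]


def _case_seed(config: PipelineConfig, i: int) -> int:
    return int(config.seed) * 10007 + 1000 + i


def make_case(config: PipelineConfig, i: int) -> Case:
    """Deterministically build case ``i``: phantom, pose, cameras."""
    cs = _case_seed(config, i)
    rng = np.random.default_rng(cs)
    params = sample_params(config.variation, rng)
    mesh = generate_vertebra(params)
    angle = np.radians(rng.uniform(0.0, config.pose.max_rotation_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-config.pose.max_translation_mm, config.pose.max_translation_mm, 3)
    truth = mesh.transformed(R, t)
    cams = make_case_cameras(config.cameras, np.zeros(3), rng)
    return Case(i, cs, params, truth, R, t, cams)


def build_demo_model(config: PipelineConfig) -> tuple[ShapeModel, np.ndarray]:
    """SSM for the demo: generated population, path annotations from the
    template phantom's analytic axes."""
    rng = np.random.default_rng(config.seed)
    meshes, params = [], []
    for _ in range(config.population_size):
        p = sample_params(config.variation, rng)
        meshes.append(generate_vertebra(p))
        params.append(p)
    return build_ssm_from_meshes(meshes, k=config.n_modes,
                                 path_endpoints=path_axes(params[0]))


def _empty_row(case: Case) -> dict:
    row = {c: np.nan for c in REPORT_COLUMNS}
    row.update(case_id=case.case_id, case_seed=case.case_seed,
               separation_deg=round(angular_separation_deg(case.cameras[0],
                                                           case.cameras[1]), 4),
               init_fallback=False, improved=False, success=False, failure_reason="")
    return row


def _finish_row(row: dict, left: PathPlan | None, right: PathPlan | None) -> dict:
    for side, plan in (("left", left), ("right", right)):
        if plan is not None and plan.min_wall_distance_mm is not None:
            row[f"{side}_min_wall_mm"] = round(plan.min_wall_distance_mm, 4)
            row[f"{side}_breach"] = bool(plan.breach)
    row["success"] = plan_success(left, right)
    if not row["success"] and not row["failure_reason"]:
        row["failure_reason"] = "breach"
    return row


def _write_report(rows: list[dict], summary: dict, config: PipelineConfig,
                  stem: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{stem}_cases.csv", index=False)
        with open(out / f"{stem}_summary.json", "w") as fh:
            json.dump({"summary": summary, "config": config.to_dict()}, fh,
                      indent=2, sort_keys=True)
        with open(out / f"{stem}_cases.jsonl", "w") as fh:
            for r in rows:
                fh.write(json.dumps({k: (None if isinstance(v, float) and np.isnan(v)
                                          else v) for k, v in r.items()},
                                    sort_keys=True) + "\n")
    return df


def _summarize(rows: list[dict], elapsed_s: float) -> dict:
    n = len(rows)
    reasons = {r: 0 for r in FAILURE_REASONS}
    for row in rows:
        if row["failure_reason"]:
            reasons[row["failure_reason"]] += 1
    succ = sum(bool(r["success"]) for r in rows)
    summary = {
        "n_cases": n,
        "n_success": succ,
        "success_rate": succ / n,
        "failure_counts": reasons,
        "elapsed_s": round(elapsed_s, 2),
    }
    for m in ("dice", "nsd", "hd95_mm", "masd_mm"):
        vals = [row[m] for row in rows if np.isfinite(row.get(m, np.nan))]
        summary[f"mean_{m}"] = float(np.mean(vals)) if vals else None
    return summary


def run_demo(config: PipelineConfig | None = None,
             model: ShapeModel | None = None) -> dict:
    """Full reconstruction-and-planning batch; see the module docstring.

    A prebuilt ``model`` skips the population/SSM stage (useful when running
    ``run_demo`` and ``run_baseline`` side by side). Per-case failures are
    categorized and recorded, never aborting the batch.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    if model is None:
        model, _ = build_demo_model(config)
    schedule = default_schedule(METRICS[config.metric](), config.optimizer,
                                config.fine_sigma_px, config.fine_iters)

    rows = []
    for i in range(config.n_cases):
        case = make_case(config, i)
        row = _empty_row(case)
        if config.verbose:
            print(f"[demo] case {i} (seed {case.case_seed})")
        targets = make_target_views(case.truth_mesh, case.cameras,
                                    sigma_scale=config.target.sigma_scale,
                                    speckle_sd=config.target.speckle_sd,
                                    read_noise_sd=config.target.read_noise_sd,
                                    seed=case.case_seed)
        detections = [
            simulate_detections(case.truth_mesh, cam,
                                pixel_noise_sd=config.detection.pixel_sd,
                                dropout_prob=config.detection.dropout_prob,
                                seed=case.case_seed + 17 * (j + 1),
                                view_id=f"view{j}")
            for j, cam in enumerate(case.cameras)
        ]
        try:
            init, report = initialize_pose(detections, case.cameras, model)
        except InitializationError:
            row["failure_reason"] = "initialization-failure"
            rows.append(row)
            continue
        except DegenerateGeometryError:
            row["failure_reason"] = "degenerate-geometry"
            rows.append(row)
            continue
        row["init_fallback"] = report.fallback
        row["n_common_landmarks"] = report.n_common

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = optimize_multiscale(model, init, targets, case.cameras,
                                         schedule=schedule, init_report=report)
        row["initial_loss"] = round(result.initial_loss, 6)
        row["final_loss"] = round(result.final_loss, 6)
        row["improved"] = result.improved

        rep = evaluate_reconstruction(result.fitted_mesh, case.truth_mesh,
                                      voxel_mm=config.voxel_mm, seed=case.case_seed)
        row["dice"] = round(rep.dice, 4)
        row["nsd"] = round(rep.nsd, 4)
        row["hd95_mm"] = round(rep.hd95_mm, 4)
        row["masd_mm"] = round(rep.masd_mm, 4)

        if not result.improved:
            row["failure_reason"] = "non-improved"
            rows.append(row)
            continue

        plans = {}
        for tmpl in model.path_annotations:
            plan = propagate_path(model, result.params, tmpl)
            plans[tmpl.side] = breach_check(plan, case.truth_mesh,
                                            seed=case.case_seed)
        rows.append(_finish_row(row, plans.get("left"), plans.get("right")))

    summary = _summarize(rows, time.time() - t0)
    df = _write_report(rows, summary, config, "demo")
    if config.verbose:
        print(f"[demo] success {summary['n_success']}/{summary['n_cases']}")
    return {"cases": df, "summary": summary, "model": model}


def run_baseline(config: PipelineConfig | None = None) -> dict:
    """Triangulation-only planning on the same cases as :func:`run_demo`.

    The 2D path-endpoint annotations are simulated as projections of the
    ground-truth pedicle axes corrupted with the configured pixel noise and
    dropped independently with the configured dropout probability; entry and
    exit are then triangulated per pedicle. No shape model or optimization
    is involved, and reconstruction metrics are left blank.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    rows = []
    for i in range(config.n_cases):
        case = make_case(config, i)
        row = _empty_row(case)
        if config.verbose:
            print(f"[baseline] case {i} (seed {case.case_seed})")
        rng = np.random.default_rng(case.case_seed + 7919)
        axes = {s: a @ case.pose_R.T + case.pose_t
                for s, a in path_axes(case.params).items()}

        plans: dict[str, PathPlan | None] = {}
        failed = False
        for side in ("left", "right"):
            entry_uv, exit_uv = [], []
            for cam in case.cameras[:2]:
                uv, _, vis = project_points(cam, axes[side])
                for store, k in ((entry_uv, 0), (exit_uv, 1)):
                    dropped = rng.random() < config.detection.dropout_prob
                    if dropped or not vis[k]:
                        store.append(None)
                    else:
                        store.append(uv[k] + rng.normal(0.0, config.detection.pixel_sd, 2))
            try:
                plan = geoplan_triangulate(entry_uv, exit_uv, case.cameras[:2], side)
            except (PlanningFailure, DegenerateGeometryError):
                plans[side] = None
                failed = True
                continue
            plans[side] = breach_check(plan, case.truth_mesh, seed=case.case_seed)
        if failed:
            row["failure_reason"] = "planning-failure"
        rows.append(_finish_row(row, plans.get("left"), plans.get("right")))

    summary = _summarize(rows, time.time() - t0)
    df = _write_report(rows, summary, config, "baseline")
    if config.verbose:
        print(f"[baseline] success {summary['n_success']}/{summary['n_cases']}")
    return {"cases": df, "summary": summary}
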