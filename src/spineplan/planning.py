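"""Transpedicular trajectory propagation, breach checking, and the
triangulation baseline.

Trajectories are annotated once on the model template as barycentric anchors
(entry and exit point each on a template face); because every fitted
instance shares the template's topology, the anchors evaluate directly on
the instantiated mesh — no per-case optimization. A planned trajectory is a
5 mm-diameter cylinder around the entry-exit axis; it is flagged as a breach
when the minimum distance from the axis segment to the pedicle wall falls
below 2.5 mm, i.e. exactly when the cylinder contacts the wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import Camera
from .geometry import (MeshProximity, barycentric_coordinates, point_segment_distance,
                       sample_surface)
from .mesh import LabeledMesh, REGIONS
from .ssm import PoseShapeParams, ShapeModel

PATH_DIAMETER_MM = 5.0
BREACH_THRESHOLD_MM = 2.5


class PlanningFailure(RuntimeError):
    """A pedicle's trajectory could not be planned (e.g. missing endpoint)."""


@dataclass
class PathTemplate:
    """Barycentric anchors of one transpedicular path on the template mesh."""

    side: str  # "left" | "right"
    entry_face: int
    entry_bary: np.ndarray  # (3,) nonneg, sums to 1
    exit_face: int
    exit_bary: np.ndarray

    def __post_init__(self):
        self.entry_bary = np.asarray(self.entry_bary, dtype=float)
        self.exit_bary = np.asarray(self.exit_bary, dtype=float)
        for w in (self.entry_bary, self.exit_bary):
            if w.shape != (3,) or w.min() < -1e-9 or abs(w.sum() - 1.0) > 1e-6:
                raise ValueError("barycentric weights must be nonnegative and sum to 1")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def evaluate(self, vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = self.entry_bary @ vertices[faces[self.entry_face]]
        x = self.exit_bary @ vertices[faces[self.exit_face]]
        return e, x

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "entry_face": int(self.entry_face),
            "entry_bary": self.entry_bary.tolist(),
            "exit_face": int(self.exit_face),
            "exit_bary": self.exit_bary.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathTemplate":
        return cls(d["side"], d["entry_face"], np.array(d["entry_bary"]),
                   d["exit_face"], np.array(d["exit_bary"]))

    @classmethod
    def from_points(cls, mesh: LabeledMesh, side: str,
                    entry_point: np.ndarray, exit_point: np.ndarray) -> "PathTemplate":
        """Anchor two 3D points to the nearest surface locations on ``mesh``."""
        prox = MeshProximity(mesh.vertices, mesh.faces)
        q, _, fi = prox.closest(np.vstack([entry_point, exit_point]))
        tri_e = mesh.vertices[mesh.faces[fi[0]]]
        tri_x = mesh.vertices[mesh.faces[fi[1]]]
        return cls(side, int(fi[0]), barycentric_coordinates(q[0], tri_e),
                   int(fi[1]), barycentric_coordinates(q[1], tri_x))


@dataclass
class PathPlan:
    """One planned transpedicular trajectory with optional breach verdict."""

    side: str
    entry: np.ndarray  # mm
    exit: np.ndarray  # mm
    diameter_mm: float = PATH_DIAMETER_MM
    min_wall_distance_mm: float | None = None
    breach: bool | None = None
    failure_reason: str | None = None

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=float).reshape(3)
        self.exit = np.asarray(self.exit, dtype=float).reshape(3)
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")
        if np.allclose(self.entry, self.exit):
            raise ValueError("entry and exit must differ")

    @property
    def ok(self) -> bool:
        return self.failure_reason is None and self.breach is False

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "entry_mm": self.entry.tolist(),
            "exit_mm": self.exit.tolist(),
            "diameter_mm": self.diameter_mm,
            "min_wall_distance_mm": self.min_wall_distance_mm,
            "breach": self.breach,
            "failure_reason": self.failure_reason,
        }


def annotate_template_paths(mesh: LabeledMesh, axes_endpoints: dict[str, np.ndarray]) -> list[PathTemplate]:
    """Anchor analytic per-side (entry, exit) endpoints onto the template."""
    return [
        PathTemplate.from_points(mesh, side, pts[0], pts[1])
        for side, pts in sorted(axes_endpoints.items())
    ]


def propagate_path(model: ShapeModel, params: PoseShapeParams,
                   template: PathTemplate) -> PathPlan:
    """Evaluate a template path on the instantiated model (no verdict yet)."""
    from .ssm import instantiate_vertices

    verts = instantiate_vertices(model, params)
    entry, exit_pt = template.evaluate(verts, model.template.faces)
    return PathPlan(template.side, entry, exit_pt)


def breach_check(
    plan: PathPlan,
    mesh: LabeledMesh,
    threshold_mm: float = BREACH_THRESHOLD_MM,
    samples_per_mm2: float = 10.0,
    seed: int = 0,
) -> PathPlan:
    """Fill in the minimum axis-to-pedicle-wall distance and breach verdict.

    The wall is the surface region labeled with the plan's pedicle side
    (faces with a majority of side-labeled vertices), sampled area-weighted
    at ``samples_per_mm2``; distance is exact point-to-segment distance to
    the entry-exit axis. Breach iff the minimum distance < ``threshold_mm``.
    """
    label = REGIONS.index(f"pedicle_{plan.side}")
    vert_mask = mesh.region_labels == label
    face_mask = vert_mask[mesh.faces].sum(axis=1) >= 2
    if not face_mask.any():
        raise ValueError(f"mesh has no pedicle_{plan.side} region labels")
    faces = mesh.faces[face_mask]
    tri = mesh.vertices[faces]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    ).sum()
    n = max(int(np.ceil(area * samples_per_mm2)), 100)
    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(mesh.vertices, faces, n, rng)
    d = point_segment_distance(pts, plan.entry, plan.exit)
    plan.min_wall_distance_mm = float(d.min())
    plan.breach = bool(plan.min_wall_distance_mm < threshold_mm)
    return plan


def geoplan_triangulate(
    entry_uv: list[np.ndarray | None],
    exit_uv: list[np.ndarray | None],
    cameras: list[Camera],
    side: str = "left",
    diameter_mm: float = PATH_DIAMETER_MM,
) -> PathPlan:
    """Baseline 3D path from independent 2D endpoint annotations per view.

    Entry and exit are triangulated independently (ray-midpoint method); a
    missing endpoint in any view raises :class:`PlanningFailure` for this
    pedicle only.
    """
    from .registration import triangulate

    if len(cameras) < 2:
        raise ValueError("need two views")
    for name, uvs in (("entry", entry_uv), ("exit", exit_uv)):
        if any(u is None for u in uvs[:2]):
            raise PlanningFailure(f"{name} endpoint missing in one view ({side})")
    e3, _ = triangulate(entry_uv[0], entry_uv[1], cameras[0], cameras[1])
    x3, _ = triangulate(exit_uv[0], exit_uv[1], cameras[0], cameras[1])
    return PathPlan(side, e3, x3, diameter_mm=diameter_mm)


def plan_success(left: PathPlan | None, right: PathPlan | None) -> bool:
    """Bipedicular success: both pedicles have a planned, non-breaching path."""
    def ok(p):
        return p is not None and p.failure_reason is None and p.breach is False
    return ok(left) and ok(right)
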