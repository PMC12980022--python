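"""Labeled triangle meshes and their on-disk formats.

A :class:`LabeledMesh` is a watertight vertebral surface with per-vertex
anatomical region labels (vertebral body, left/right pedicle, posterior
processes), ten named anatomical landmarks stored as vertex indices, and —
when known — the two ground-truth pedicle axes as 3D segments. Geometry goes
through trimesh (PLY/OBJ); labels, landmarks and axes travel in a sidecar
JSON keyed by vertex index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

REGIONS = ("body", "pedicle_left", "pedicle_right", "process")

LANDMARK_NAMES = (
    "body_anterior",
    "body_left",
    "body_right",
    "endplate_superior",
    "endplate_inferior",
    "spinous_tip",
    "transverse_left",
    "transverse_right",
    "pedicle_left_posterior",
    "pedicle_right_posterior",
)

BACKUP_LANDMARK_NAMES = ("centroid", "superior", "inferior", "left", "right")


class MeshValidationError(ValueError):
    pass


@dataclass
class LabeledMesh:
    """Triangle mesh with anatomical annotations (units: mm)."""

    vertices: np.ndarray  # (N, 3) float
    faces: np.ndarray  # (F, 3) int
    region_labels: np.ndarray  # (N,) int, index into REGIONS
    landmark_indices: dict[str, int] = field(default_factory=dict)
    pedicle_axes: dict[str, np.ndarray] | None = None  # side -> (2, 3) segment

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (N, 3)")
        if len(self.region_labels) != len(self.vertices):
            raise MeshValidationError("one region label per vertex required")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshValidationError("face indices out of range")
        if self.landmark_indices:
            if set(self.landmark_indices) != set(LANDMARK_NAMES):
                raise MeshValidationError(
                    "landmark_indices must carry exactly the 10 canonical names"
                )
            idx = np.array(list(self.landmark_indices.values()))
            if idx.min() < 0 or idx.max() >= len(self.vertices):
                raise MeshValidationError("landmark index out of range")

    # -- derived ----------------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def landmarks_3d(self) -> dict[str, np.ndarray]:
        return {k: self.vertices[v] for k, v in self.landmark_indices.items()}

    def region_mask(self, region: str) -> np.ndarray:
        return self.region_labels == REGIONS.index(region)

    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def validate(self) -> None:
        """Enforce the full invariant set (watertight, non-degenerate faces)."""
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise MeshValidationError("mesh is not watertight")
        if tm.area_faces.min() <= 0:
            raise MeshValidationError("degenerate (zero-area) face present")

    def transformed(self, R: np.ndarray, t: np.ndarray, scale: float = 1.0) -> "LabeledMesh":
        """Apply ``x -> scale * R x + t`` to geometry and axes; labels carry over."""
        v = scale * self.vertices @ np.asarray(R).T + np.asarray(t)
        axes = None
        if self.pedicle_axes is not None:
            axes = {
                s: scale * seg @ np.asarray(R).T + np.asarray(t)
                for s, seg in self.pedicle_axes.items()
            }
        return LabeledMesh(v, self.faces.copy(), self.region_labels.copy(),
                           dict(self.landmark_indices), axes)

    def copy(self) -> "LabeledMesh":
        return self.transformed(np.eye(3), np.zeros(3))

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write geometry (PLY or OBJ by extension) plus a `.labels.json` sidecar."""
        path = Path(path)
        self.as_trimesh().export(path)
        sidecar = {
            "region_labels": self.region_labels.tolist(),
            "landmark_indices": {k: int(v) for k, v in self.landmark_indices.items()},
            "pedicle_axes": None
            if self.pedicle_axes is None
            else {s: np.asarray(a).tolist() for s, a in self.pedicle_axes.items()},
        }
        path.with_suffix(path.suffix + ".labels.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "LabeledMesh":
        path = Path(path)
        tm = trimesh.load(path, process=False, force="mesh")
        sidecar_path = path.with_suffix(path.suffix + ".labels.json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            labels = np.asarray(meta["region_labels"], dtype=int)
            lmk = {k: int(v) for k, v in meta.get("landmark_indices", {}).items()}
            axes = meta.get("pedicle_axes")
            if axes is not None:
                axes = {s: np.asarray(a, dtype=float) for s, a in axes.items()}
        else:
            labels = np.zeros(len(tm.vertices), dtype=int)
            lmk, axes = {}, None
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), labels, lmk, axes)
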