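"""Simulated 2D landmark detections and radiograph-like target images.

These stand in for a landmark-detection network and for physics-based
radiograph synthesis: detections are exact projections of the ground-truth
3D landmarks corrupted by Gaussian pixel noise and independent dropout, and
target images are splat renderings of the ground-truth mesh made with a
deliberately *wider* splat than the registration renderer plus multiplicative
speckle and additive read noise, so self-registration is never trivially
perfect (inverse-crime mitigation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import Camera, project_points
from .mesh import BACKUP_LANDMARK_NAMES, LANDMARK_NAMES, LabeledMesh
from .rendering import SplatConfig, _subsample_indices, mean_edge_length, splat_render

_ALLOWED = set(LANDMARK_NAMES) | set(BACKUP_LANDMARK_NAMES)


@dataclass
class DetectionSet:
    """Per-view 2D landmark detections (pixel coordinates)."""

    view_id: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    confidences: dict[str, float] = field(default_factory=dict)
    present: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.positions) - _ALLOWED
        if bad:
            raise ValueError(f"unknown landmark names: {sorted(bad)}")

    def has(self, name: str) -> bool:
        return bool(self.present.get(name, False))

    def position(self, name: str) -> np.ndarray:
        if not self.has(name):
            raise KeyError(f"landmark {name!r} not present in view {self.view_id}")
        return np.asarray(self.positions[name], dtype=float)

    def add(self, name: str, uv, confidence: float, present: bool = True):
        if name not in _ALLOWED:
            raise ValueError(f"unknown landmark name {name!r}")
        self.positions[name] = np.asarray(uv, dtype=float)
        self.confidences[name] = float(confidence)
        self.present[name] = bool(present)


def detections_to_csv(detections: list[DetectionSet], path: str | Path) -> None:
    rows = []
    for d in detections:
        for name, uv in d.positions.items():
            rows.append({
                "view_id": d.view_id, "landmark_name": name,
                "u_px": uv[0], "v_px": uv[1],
                "confidence": d.confidences.get(name, np.nan),
                "present": d.present.get(name, False),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def detections_from_csv(path: str | Path) -> list[DetectionSet]:
    df = pd.read_csv(path)
    out = []
    for vid, grp in df.groupby("view_id", sort=False):
        d = DetectionSet(str(vid))
        for _, r in grp.iterrows():
            d.add(r["landmark_name"], (r["u_px"], r["v_px"]),
                  r["confidence"], bool(r["present"]))
        out.append(d)
    return out


def simulate_detections(
    mesh: LabeledMesh,
    camera: Camera,
    pixel_noise_sd: float = 0.0,
    dropout_prob: float = 0.0,
    seed: int = 0,
    view_id: str = "view0",
) -> DetectionSet:
    """Project the mesh's true landmarks and corrupt them.

    Each anatomical landmark gets isotropic Gaussian pixel noise and is
    dropped independently with probability ``dropout_prob`` (confidence is
    1 minus the dropout draw, so barely-kept landmarks score low). Landmarks
    behind the camera or off the raster are marked absent. The five backup
    landmarks are derived from the projected silhouette's bounding box and
    never participate in dropout.
    """
    if pixel_noise_sd < 0 or not (0.0 <= dropout_prob <= 1.0):
        raise ValueError("invalid noise settings")
    rng = np.random.default_rng(seed)
    det = DetectionSet(view_id)

    pts = np.array([mesh.vertices[mesh.landmark_indices[n]] for n in LANDMARK_NAMES])
    uv, _, vis = project_points(camera, pts)
    for i, name in enumerate(LANDMARK_NAMES):
        draw = rng.random()
        noise = rng.normal(0.0, pixel_noise_sd, 2) if pixel_noise_sd > 0 else np.zeros(2)
        if not vis[i]:
            det.add(name, (np.nan, np.nan), 0.0, present=False)
            continue
        p = uv[i] + noise
        keep = draw >= dropout_prob
        inside = bool(camera.contains(p)[0])
        det.add(name, p, max(1.0 - draw, 0.0), present=keep and inside)

    all_uv, _, all_vis = project_points(camera, mesh.vertices)
    sil = all_uv[all_vis]
    if len(sil):
        lo = sil.min(axis=0)
        hi = sil.max(axis=0)
        c = 0.5 * (lo + hi)
        backup = {
            "centroid": c,
            "superior": np.array([c[0], lo[1]]),
            "inferior": np.array([c[0], hi[1]]),
            "left": np.array([lo[0], c[1]]),
            "right": np.array([hi[0], c[1]]),
        }
        for name, p in backup.items():
            if pixel_noise_sd > 0:
                p = p + rng.normal(0.0, pixel_noise_sd, 2)
            det.add(name, p, 1.0, present=bool(camera.contains(p)[0]))
    else:
        for name in BACKUP_LANDMARK_NAMES:
            det.add(name, (np.nan, np.nan), 0.0, present=False)
    return det


def make_target_views(
    mesh: LabeledMesh,
    cameras: list[Camera],
    sigma_scale: float = 1.5,
    speckle_sd: float = 0.05,
    read_noise_sd: float = 0.01,
    seed: int = 0,
    splat: SplatConfig | None = None,
) -> list[np.ndarray]:
    """Render ground-truth target images for the registration stage.

    The splat width is ``sigma_scale`` times the mesh's mean edge length
    (the registration default uses scale 1), and multiplicative speckle plus
    Gaussian read noise are added before renormalization to [0, 1].
    """
    if not cameras:
        raise ValueError("need at least one camera")
    rng = np.random.default_rng(seed)
    cfg = splat or SplatConfig()
    sigma = sigma_scale * mean_edge_length(mesh.vertices, mesh.faces)
    idx = _subsample_indices(len(mesh.vertices), cfg.max_splats)
    pts = mesh.vertices[idx]
    out = []
    for cam in cameras:
        uv, z, _ = project_points(cam, pts)
        img = splat_render(uv, z, cam, cfg, sigma_mm=sigma).image
        if speckle_sd > 0:
            img = img * (1.0 + rng.normal(0.0, speckle_sd, img.shape))
        if read_noise_sd > 0:
            img = img + rng.normal(0.0, read_noise_sd, img.shape)
        img = np.clip(img, 0.0, None)
        m = img.max()
        out.append(img / m if m > 0 else img)
    return out
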