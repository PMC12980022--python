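"""Pinhole camera model for radiograph-like projections.

The projection matrix is P = K [R_cam | t_cam]; a world point X maps to
homogeneous image coordinates x~ = P [X; 1] and pixel coordinates
(u, v) = (x~_0 / x~_2, x~_1 / x~_2), with x~_2 the depth along the optical
axis. P is always derived from (K, R_cam, t_cam) — never stored separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

BEHIND_EPS = 1e-6


@dataclass
class Camera:
    K: np.ndarray  # (3, 3) intrinsics, pixels
    R: np.ndarray  # (3, 3) world-to-camera rotation
    t: np.ndarray  # (3,) translation, mm
    height: int
    width: int
    pixel_spacing_mm: float = 1.0

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not (np.allclose(np.tril(self.K, -1), 0.0) and np.all(np.diag(self.K) > 0)):
            raise ValueError("K must be upper-triangular with positive diagonal")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9) or np.linalg.det(self.R) < 0:
            raise ValueError("R_cam must be a rotation matrix (within 1e-9)")

    # -- geometry -----------------------------------------------------------
    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix K [R | t]."""
        return self.K @ np.hstack([self.R, self.t[:, None]])

    @property
    def center(self) -> np.ndarray:
        """Camera (X-ray source) position in world coordinates."""
        return -self.R.T @ self.t

    @property
    def view_direction(self) -> np.ndarray:
        """Unit optical-axis direction in world coordinates."""
        return self.R.T @ np.array([0.0, 0.0, 1.0])

    def ray(self, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Back-project a pixel to a world ray (origin, unit direction)."""
        u, v = float(uv[0]), float(uv[1])
        d_cam = np.linalg.solve(self.K, np.array([u, v, 1.0]))
        d = self.R.T @ d_cam
        return self.center, d / np.linalg.norm(d)

    def contains(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        return (
            (uv[:, 0] >= 0) & (uv[:, 0] <= self.width - 1)
            & (uv[:, 1] >= 0) & (uv[:, 1] <= self.height - 1)
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "K": self.K.tolist(),
            "R": self.R.tolist(),
            "t": self.t.tolist(),
            "height": self.height,
            "width": self.width,
            "pixel_spacing_mm": self.pixel_spacing_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Camera":
        return cls(np.array(d["K"]), np.array(d["R"]), np.array(d["t"]),
                   int(d["height"]), int(d["width"]),
                   float(d.get("pixel_spacing_mm", 1.0)))


def save_cameras(cameras: list[Camera], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in cameras], indent=1))


def load_cameras(path: str | Path) -> list[Camera]:
    return [Camera.from_dict(d) for d in json.loads(Path(path).read_text())]


def project_points(camera: Camera, points3d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project world points through the pinhole model.

    Returns ``(uv, depth, visible)``: pixel coordinates (n, 2), depth x~_2
    along the optical axis (mm), and a mask flagging points with depth above
    the behind-camera epsilon. Pixel coordinates of non-visible points are
    NaN.
    """
    X = np.atleast_2d(np.asarray(points3d, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("points must be finite")
    h = camera.P @ np.hstack([X, np.ones((len(X), 1))]).T
    z = h[2]
    visible = z > BEHIND_EPS
    uv = np.full((len(X), 2), np.nan)
    uv[visible, 0] = h[0, visible] / z[visible]
    uv[visible, 1] = h[1, visible] / z[visible]
    return uv, z, visible


def look_at_camera(
    center: np.ndarray,
    azimuth_deg: float,
    elevation_deg: float,
    distance_mm: float = 600.0,
    focal_px: float = 640.0,
    image_size: tuple[int, int] = (128, 128),
    pixel_spacing_mm: float = 1.0,
) -> Camera:
    """Camera on an orbit around ``center``, optical axis through ``center``.

    Azimuth 0 looks along +y (anteroposterior for the canonical phantom
    frame); azimuth 90 looks along -x (lateral). Elevation tilts the source
    toward +z. The world up-reference is +z.
    """
    center = np.asarray(center, dtype=float)
    az = np.radians(azimuth_deg)
    el = np.radians(elevation_deg)
    # unit vector from source toward the orbit center
    d = np.array([np.sin(az) * np.cos(el), -np.cos(az) * np.cos(el), np.sin(el)])
    src = center - distance_mm * d
    z_axis = d
    up = np.array([0.0, 0.0, 1.0])
    if abs(z_axis @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    x_axis = np.cross(up, z_axis)
    x_axis /= np.linalg.norm(x_axis)
    y_axis = np.cross(z_axis, x_axis)
    R = np.vstack([x_axis, y_axis, z_axis])  # world -> camera
    t = -R @ src
    H, W = image_size
    K = np.array([
        [focal_px, 0.0, (W - 1) / 2.0],
        [0.0, focal_px, (H - 1) / 2.0],
        [0.0, 0.0, 1.0],
    ])
    return Camera(K, R, t, H, W, pixel_spacing_mm)


def angular_separation_deg(cam_a: Camera, cam_b: Camera) -> float:
    """Angle between the two optical axes, in degrees."""
    c = float(np.clip(cam_a.view_direction @ cam_b.view_direction, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))
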