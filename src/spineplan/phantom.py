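"""Parametric vertebra phantoms and phantom populations.

The phantom is a schematic vertebra in a canonical frame (x: left-to-right,
y: posterior-to-anterior, z: inferior-to-superior): an elliptic-cylinder
vertebral body, two cylindrical (capsule) pedicles splaying posterolaterally,
a capsule spinous process and two transverse processes joined by laminae.
It is deliberately schematic rather than anatomical — its value is that every
geometric quantity downstream code must recover (region labels, landmark
positions, pedicle axes, wall clearances) is known analytically.

Surfaces are extracted by marching cubes from the union signed-distance
field; per-vertex region labels are the arg-min over the component fields,
so any surface vertex *not* labeled pedicle is guaranteed to lie at least
one pedicle radius from the pedicle centerline (up to voxelization error).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.measure import marching_cubes

from .geometry import MeshProximity, point_segment_distance
from .mesh import LANDMARK_NAMES, LabeledMesh, REGIONS


class PhantomGeometryError(ValueError):
    pass


@dataclass
class PhantomParams:
    """Generative parameters of the vertebra phantom (lengths in mm)."""

    body_a: float = 20.0          # body semi-axis, left-right
    body_b: float = 15.0          # body semi-axis, posterior-anterior
    body_height: float = 28.0     # body height, inferior-superior
    pedicle_radius: float = 5.0
    pedicle_length: float = 14.0
    pedicle_inclination_deg: float = 20.0  # lateral splay of the pedicle axes
    spinous_length: float = 22.0
    transverse_length: float = 16.0
    scale: float = 1.0            # global isotropic scale, applied last

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if name == "pedicle_inclination_deg":
                continue
            if v <= 0:
                raise PhantomGeometryError(f"{name} must be positive, got {v}")
        if self.pedicle_radius <= 2.5:
            raise PhantomGeometryError(
                "pedicle_radius must exceed 2.5 mm so a centered 5 mm path "
                "cannot breach by construction"
            )
        if self.pedicle_radius > 0.6 * self.body_b:
            raise PhantomGeometryError("pedicle_radius too large for the body")
        if not (0.0 <= self.pedicle_inclination_deg <= 45.0):
            raise PhantomGeometryError("pedicle inclination must be in [0, 45] deg")


def _capsule_sdf(pts: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    return point_segment_distance(pts, a, b) - r


def _phantom_fields(params: PhantomParams):
    """Component pseudo-SDFs and the analytic skeleton of the phantom.

    Returns (sdf functions per region, pedicle axes, landmark points,
    path axis endpoints) in the unscaled canonical frame.
    """
    p = params
    alpha = np.radians(p.pedicle_inclination_deg)
    # pedicle axes: from inside the posterior body wall, posterolaterally
    x_off = 0.45 * p.body_a
    y0 = -0.65 * p.body_b
    axes = {}
    for side, s in (("left", -1.0), ("right", 1.0)):
        d = np.array([s * np.sin(alpha), -np.cos(alpha), 0.0])
        p0 = np.array([s * x_off, y0, 0.0])
        axes[side] = np.vstack([p0, p0 + p.pedicle_length * d])

    lam_y = axes["left"][1][1] - 0.6 * p.pedicle_radius  # lamina plane, posterior of pedicles
    s_root = np.array([0.0, lam_y, 0.0])
    s_tip = s_root + np.array([0.0, -p.spinous_length, 0.0])
    r_arch = 3.5
    tr = {}
    for side, s in (("left", -1.0), ("right", 1.0)):
        start = np.array([axes[side][1][0], lam_y, 0.0])
        tr[side] = np.vstack([start, start + np.array([s * p.transverse_length, 0.0, 0.0])])

    def body_sdf(pts):
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        ell = (np.sqrt((x / p.body_a) ** 2 + (y / p.body_b) ** 2) - 1.0) * min(p.body_a, p.body_b)
        return np.maximum(ell, np.abs(z) - p.body_height / 2.0)

    def ped_sdf(side):
        return lambda pts: _capsule_sdf(pts, axes[side][0], axes[side][1], p.pedicle_radius)

    def process_sdf(pts):
        d = _capsule_sdf(pts, s_root, s_tip, r_arch)
        for side in ("left", "right"):
            d = np.minimum(d, _capsule_sdf(pts, tr[side][0], tr[side][1], 3.0))
            d = np.minimum(d, _capsule_sdf(pts, axes[side][1], s_root, r_arch))
        return d

    sdfs = {
        "body": body_sdf,
        "pedicle_left": ped_sdf("left"),
        "pedicle_right": ped_sdf("right"),
        "process": process_sdf,
    }

    landmarks = {
        "body_anterior": np.array([0.0, p.body_b, 0.0]),
        "body_left": np.array([-p.body_a, 0.0, 0.0]),
        "body_right": np.array([p.body_a, 0.0, 0.0]),
        "endplate_superior": np.array([0.0, 0.0, p.body_height / 2.0]),
        "endplate_inferior": np.array([0.0, 0.0, -p.body_height / 2.0]),
        "spinous_tip": s_tip + np.array([0.0, -r_arch, 0.0]),
        "transverse_left": tr["left"][1] + np.array([-3.0, 0.0, 0.0]),
        "transverse_right": tr["right"][1] + np.array([3.0, 0.0, 0.0]),
        "pedicle_left_posterior": 0.5 * (axes["left"][0] + axes["left"][1])
        + np.array([0.0, 0.0, p.pedicle_radius]),
        "pedicle_right_posterior": 0.5 * (axes["right"][0] + axes["right"][1])
        + np.array([0.0, 0.0, p.pedicle_radius]),
    }
    return sdfs, axes, landmarks


def _path_axis_endpoints(params: PhantomParams, axes: dict) -> dict:
    """Analytic transpedicular axis per side: posterior pedicle entry to the
    anterior body cortex, passing along the pedicle centerline."""
    p = params
    out = {}
    for side in ("left", "right"):
        p0, p1 = axes[side]
        d = (p1 - p0) / np.linalg.norm(p1 - p0)
        entry = p1 + 0.8 * p.pedicle_radius * d
        # intersect the line p0 + t*(-d) with the body ellipse (z = 0 plane)
        A = (d[0] / p.body_a) ** 2 + (d[1] / p.body_b) ** 2
        B = -2.0 * (p0[0] * d[0] / p.body_a**2 + p0[1] * d[1] / p.body_b**2)
        C = (p0[0] / p.body_a) ** 2 + (p0[1] / p.body_b) ** 2 - 1.0
        disc = B * B - 4 * A * C
        t = (-B + np.sqrt(max(disc, 0.0))) / (2 * A)
        exit_pt = p0 - t * d
        out[side] = np.vstack([entry, exit_pt])
    return out


def generate_vertebra(
    params: PhantomParams | None = None,
    seed: int | None = None,
    grid_spacing: float = 1.8,
) -> LabeledMesh:
    """Build one watertight labeled phantom.

    ``seed`` is accepted for API symmetry but never used: the mesh is a
    deterministic function of ``params`` (randomness lives in
    :func:`sample_population` and the detection/image simulators).
    """
    p = params or PhantomParams()
    p.validate()
    sdfs, axes, landmarks = _phantom_fields(p)

    lo = np.array([-(p.body_a + p.transverse_length + 8),
                   -(0.65 * p.body_b + p.pedicle_length + p.spinous_length + 12),
                   -(p.body_height / 2 + 8)])
    hi = np.array([p.body_a + p.transverse_length + 8, p.body_b + 8, p.body_height / 2 + 8])
    # tiny irrational offset keeps the level set off grid points
    grids = [np.arange(lo[i], hi[i] + grid_spacing, grid_spacing) + 1.37e-4 for i in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    fields = np.stack([sdfs[r](pts) for r in REGIONS])
    union = fields.min(axis=0).reshape(gx.shape)
    if union.min() > 0:
        raise PhantomGeometryError("parameters produce an empty phantom")

    verts, faces, _, _ = marching_cubes(union, level=0.0, spacing=(grid_spacing,) * 3)
    verts = verts + np.array([grids[0][0], grids[1][0], grids[2][0]])

    vert_fields = np.stack([sdfs[r](verts) for r in REGIONS])
    labels = vert_fields.argmin(axis=0)
    # The pedicle wall means the tube wall: capsule end caps (crossed by any
    # transpedicular path at entry) are relabeled to the nearest other region,
    # so a centered path of radius < pedicle_radius cannot breach by
    # construction.
    for side in ("left", "right"):
        li = REGIONS.index(f"pedicle_{side}")
        p0, p1 = axes[side]
        d = p1 - p0
        tax = (verts - p0) @ d / (d @ d)
        cap = (labels == li) & ((tax < 0.0) | (tax > 1.0))
        if cap.any():
            others = [i for i in range(len(REGIONS)) if i != li]
            labels[cap] = np.array(others)[vert_fields[others][:, cap].argmin(axis=0)]

    prox = MeshProximity(verts, faces)
    lmk_indices = {}
    for name in LANDMARK_NAMES:
        q, _, _ = prox.closest(landmarks[name][None, :])
        lmk_indices[name] = int(np.linalg.norm(verts - q[0], axis=1).argmin())

    mesh = LabeledMesh(
        verts, faces, labels, lmk_indices,
        {s: a.copy() for s, a in axes.items()},
    )
    if p.scale != 1.0:
        mesh = mesh.transformed(np.eye(3), np.zeros(3), scale=p.scale)
    mesh.validate()
    return mesh


def path_axes(params: PhantomParams | None = None) -> dict[str, np.ndarray]:
    """Ground-truth transpedicular axis endpoints (entry, exit) per side, mm."""
    p = params or PhantomParams()
    _, axes, _ = _phantom_fields(p)
    out = _path_axis_endpoints(p, axes)
    if p.scale != 1.0:
        out = {s: a * p.scale for s, a in out.items()}
    return out


#: population variation used for demo SSMs: (parameter, standard deviation)
DEFAULT_VARIATION: dict[str, float] = {
    "body_a": 1.2,
    "body_b": 0.9,
    "body_height": 1.6,
    "pedicle_radius": 0.25,
    "pedicle_length": 0.9,
    "pedicle_inclination_deg": 2.5,
    "spinous_length": 1.8,
    "transverse_length": 1.2,
}


def sample_params(
    variation: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> PhantomParams:
    rng = rng or np.random.default_rng()
    variation = DEFAULT_VARIATION if variation is None else variation
    p = PhantomParams()
    for name, sd in variation.items():
        if sd == 0:
            continue
        base = getattr(p, name)
        val = rng.normal(base, sd)
        if name == "pedicle_radius":
            val = max(val, 2.7)  # keep the by-construction no-breach invariant
        elif name != "pedicle_inclination_deg":
            val = max(val, 0.25 * base)
        setattr(p, name, float(val))
    p.validate()
    return p


def sample_population(
    n: int,
    variation: dict[str, float] | None = None,
    seed: int = 0,
    grid_spacing: float = 1.8,
) -> tuple[list[LabeledMesh], list[PhantomParams]]:
    """Draw ``n`` phantoms with independently perturbed parameters."""
    if n < 2:
        raise ValueError("population needs n >= 2")
    rng = np.random.default_rng(seed)
    params = [sample_params(variation, rng) for _ in range(n)]
    meshes = [generate_vertebra(p, grid_spacing=grid_spacing) for p in params]
    return meshes, params
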