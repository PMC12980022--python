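"""Reconstruction and planning metrics.

Volumetric overlap (DICE) is computed on a solid voxelization of the two
watertight surfaces over a shared grid; the surface metrics (NSD, HD-95,
MASD) are computed on seeded area-weighted surface samples in both
directions, which makes them symmetric by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .geometry import geodesic_angle_deg, sample_surface
from .mesh import LabeledMesh

DEFAULT_VOXEL_MM = 0.5
DEFAULT_NSD_TAU_MM = 1.0
DEFAULT_SURFACE_SAMPLES = 10_000


@dataclass
class MetricReport:
    """Flat per-case metric record (CSV row / JSON object)."""

    dice: float = np.nan
    nsd: float = np.nan
    hd95_mm: float = np.nan
    masd_mm: float = np.nan
    rotation_error_deg: float = np.nan
    translation_error_mm: float = np.nan
    coeff_rmse: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


class VoxelizationError(ValueError):
    pass


def voxelize(
    mesh: LabeledMesh,
    spacing_mm: float = DEFAULT_VOXEL_MM,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solid voxelization: a voxel is set iff its center lies inside the mesh.

    Inside-ness is decided by crossing parity of a vertical (z) ray per grid
    column; the grid origin carries a tiny irrational offset so rays avoid
    triangle edges. Requires a watertight mesh. Returns (occupancy, origin):
    occupancy[i, j, k] covers center origin + spacing * (i, j, k).
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    tm = mesh.as_trimesh()
    if not tm.is_watertight:
        open_edges = len(tm.edges) - len(tm.face_adjacency_edges) * 2
        raise VoxelizationError(
            f"mesh is not watertight ({max(open_edges, 1)} unmatched edge slots)"
        )
    v, f = mesh.vertices, mesh.faces
    if bounds is None:
        lo, hi = v.min(axis=0), v.max(axis=0)
    else:
        lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    origin = lo - spacing_mm + np.array([1.7e-5, 2.9e-5, 0.0])  # one-voxel margin
    n = np.ceil((hi - origin) / spacing_mm).astype(int) + 2
    nx, ny, nz = int(n[0]), int(n[1]), int(n[2])
    xs = origin[0] + spacing_mm * np.arange(nx)
    ys = origin[1] + spacing_mm * np.arange(ny)
    zs = origin[2] + spacing_mm * np.arange(nz)

    # crossing z per (ix, iy) column, accumulated face by face
    tri = v[f]
    crossings: dict[tuple[int, int], list[float]] = {}
    for a, b, c in tri:
        xmin, xmax = min(a[0], b[0], c[0]), max(a[0], b[0], c[0])
        ymin, ymax = min(a[1], b[1], c[1]), max(a[1], b[1], c[1])
        i0 = max(int(np.ceil((xmin - origin[0]) / spacing_mm)), 0)
        i1 = min(int(np.floor((xmax - origin[0]) / spacing_mm)), nx - 1)
        j0 = max(int(np.ceil((ymin - origin[1]) / spacing_mm)), 0)
        j1 = min(int(np.floor((ymax - origin[1]) / spacing_mm)), ny - 1)
        if i1 < i0 or j1 < j0:
            continue
        px = xs[i0:i1 + 1]
        py = ys[j0:j1 + 1]
        gx, gy = np.meshgrid(px, py, indexing="ij")
        # 2D barycentric test in the xy projection
        d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if abs(d) < 1e-15:
            continue  # vertical triangle: no z crossing from this face
        w0 = ((b[1] - c[1]) * (gx - c[0]) + (c[0] - b[0]) * (gy - c[1])) / d
        w1 = ((c[1] - a[1]) * (gx - c[0]) + (a[0] - c[0]) * (gy - c[1])) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        zc = w0 * a[2] + w1 * b[2] + w2 * c[2]
        ii, jj = np.nonzero(inside)
        for i_, j_, z_ in zip(ii, jj, zc[inside]):
            crossings.setdefault((i0 + i_, j0 + j_), []).append(float(z_))

    occ = np.zeros((nx, ny, nz), dtype=bool)
    for (i, j), zs_cross in crossings.items():
        zs_cross.sort()
        if len(zs_cross) % 2:
            # numerically grazing hit; drop the unpaired crossing
            zs_cross = zs_cross[:-1]
        for lo_z, hi_z in zip(zs_cross[::2], zs_cross[1::2]):
            k0 = int(np.ceil((lo_z - origin[2]) / spacing_mm))
            k1 = int(np.floor((hi_z - origin[2]) / spacing_mm))
            if k1 >= k0:
                occ[i, j, max(k0, 0):min(k1, nz - 1) + 1] = True
    return occ, origin


def dice(vol_a: np.ndarray, vol_b: np.ndarray) -> float:
    """Volumetric overlap 2|A∩B| / (|A| + |B|) on a shared grid."""
    a = np.asarray(vol_a, dtype=bool)
    b = np.asarray(vol_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("volumes must share one grid")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        warnings.warn("both volumes empty; DICE defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _surface_points(mesh: LabeledMesh, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(mesh.vertices, mesh.faces, n, rng)
    return pts


def _directed_distances(pts_a: np.ndarray, pts_b: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(pts_b).query(pts_a)
    return d


def _surface_distances(mesh_a: LabeledMesh, mesh_b: LabeledMesh,
                       n_samples: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distances from area-weighted samples of each surface to the
    *other mesh's surface* (not to its sample cloud), in both directions."""
    from .geometry import MeshProximity

    pa = _surface_points(mesh_a, n_samples, seed)
    pb = _surface_points(mesh_b, n_samples, seed + 1)
    _, dab, _ = MeshProximity(mesh_b.vertices, mesh_b.faces).closest(pa)
    _, dba, _ = MeshProximity(mesh_a.vertices, mesh_a.faces).closest(pb)
    return dab, dba


def nsd(
    mesh_a: LabeledMesh,
    mesh_b: LabeledMesh,
    tau_mm: float = DEFAULT_NSD_TAU_MM,
    n_samples: int = DEFAULT_SURFACE_SAMPLES,
    seed: int = 0,
) -> float:
    """Normalized Surface Dice: fraction of surface (both directions,
    area-weighted samples, exact sample-to-surface distances) within
    ``tau_mm`` of the other surface."""
    if tau_mm <= 0:
        raise ValueError("tau must be positive")
    dab, dba = _surface_distances(mesh_a, mesh_b, n_samples, seed)
    return float(((dab <= tau_mm).sum() + (dba <= tau_mm).sum()) / (len(dab) + len(dba)))


def hd95(
    mesh_a: LabeledMesh,
    mesh_b: LabeledMesh,
    n_samples: int = DEFAULT_SURFACE_SAMPLES,
    seed: int = 0,
) -> float:
    """95th-percentile symmetric Hausdorff distance: surface samples against
    the exact opposing surface (mm)."""
    dab, dba = _surface_distances(mesh_a, mesh_b, n_samples, seed)
    return float(max(np.percentile(dab, 95), np.percentile(dba, 95)))


def masd(
    mesh_a: LabeledMesh,
    mesh_b: LabeledMesh,
    n_samples: int = DEFAULT_SURFACE_SAMPLES,
    seed: int = 0,
) -> float:
    """Mean average surface distance: symmetric mean of directed means of
    exact sample-to-surface distances (mm)."""
    dab, dba = _surface_distances(mesh_a, mesh_b, n_samples, seed)
    return float(0.5 * (dab.mean() + dba.mean()))


def point_set_hd95(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    """HD-95 directly on point sets (used for oracle cross-checks)."""
    return float(max(
        np.percentile(_directed_distances(pts_a, pts_b), 95),
        np.percentile(_directed_distances(pts_b, pts_a), 95),
    ))


def point_set_masd(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    return float(0.5 * (_directed_distances(pts_a, pts_b).mean()
                        + _directed_distances(pts_b, pts_a).mean()))


def pose_error(est, truth) -> tuple[float, float, float]:
    """(rotation geodesic error deg, translation error mm, coeff RMSE std units)."""
    rot = geodesic_angle_deg(est.R, truth.R)
    trans = float(np.linalg.norm(est.translation - truth.translation))
    if est.coeffs.size != truth.coeffs.size:
        raise ValueError("parameter vectors belong to different models")
    rmse = float(np.sqrt(np.mean((est.coeffs - truth.coeffs) ** 2))) if est.coeffs.size else 0.0
    return rot, trans, rmse


def evaluate_reconstruction(
    fitted: LabeledMesh,
    truth: LabeledMesh,
    est_params=None,
    truth_params=None,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    tau_mm: float = DEFAULT_NSD_TAU_MM,
    n_samples: int = DEFAULT_SURFACE_SAMPLES,
    seed: int = 0,
) -> MetricReport:
    """All reconstruction metrics for one case on shared grids/samples."""
    from .ssm import voxelize_common

    occ_a, occ_b = voxelize_common(fitted, truth, voxel_mm)
    rep = MetricReport(
        dice=dice(occ_a, occ_b),
        nsd=nsd(fitted, truth, tau_mm, n_samples, seed),
        hd95_mm=hd95(fitted, truth, n_samples, seed),
        masd_mm=masd(fitted, truth, n_samples, seed),
    )
    if est_params is not None and truth_params is not None:
        rep.rotation_error_deg, rep.translation_error_mm, rep.coeff_rmse = pose_error(
            est_params, truth_params
        )
    return rep
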