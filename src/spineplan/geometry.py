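"""Low-level geometric primitives shared across the package.

Rotations are parameterized as axis-angle (rotation-vector) 3-vectors; the
exponential map and its exact Jacobian are needed because the registration
stage differentiates rendered images with respect to pose.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

_EPS = 1e-12


def rotvec_to_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Exponential map from so(3) (axis-angle vector) to SO(3)."""
    return Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()


def rotation_matrix_derivatives(rotvec: np.ndarray) -> np.ndarray:
    """Exact partial derivatives dR/domega_j of the exponential map.

    Uses the closed form of Gallego & Yezzi: for theta = |omega| > 0,

        dR/domega_j = (omega_j [omega]_x + [omega x (I - R) e_j]_x) R / theta^2

    and dR/domega_j = [e_j]_x in the limit omega -> 0.

    Returns an array of shape (3, 3, 3); entry [j] is dR/domega_j.
    """
    omega = np.asarray(rotvec, dtype=float)
    theta2 = float(omega @ omega)
    if theta2 < 1e-16:
        out = np.empty((3, 3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = 1.0
            out[j] = skew(e)
        return out
    R = rotvec_to_matrix(omega)
    out = np.empty((3, 3, 3))
    I = np.eye(3)
    for j in range(3):
        e = I[j]
        v = np.cross(omega, (I - R) @ e)
        out[j] = (omega[j] * skew(omega) + skew(v)) @ R / theta2
    return out


def skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def geodesic_angle_deg(R_a: np.ndarray, R_b: np.ndarray) -> float:
    """Geodesic distance between two rotation matrices, in degrees."""
    R = R_a.T @ R_b
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def umeyama(
    source: np.ndarray, target: np.ndarray, with_scale: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares similarity transform ``target ~ s * R @ source + t``.

    Closed-form (Umeyama 1991) with proper-rotation enforcement; ``with_scale``
    False returns s = 1 (rigid fit, Kabsch).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.shape[0] < 3:
        raise ValueError("umeyama needs two equal (n>=3, 3) point arrays")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    sc = src - mu_s
    tc = tgt - mu_t
    cov = tc.T @ sc / src.shape[0]
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_s = (sc**2).sum() / src.shape[0]
        s = float((D * np.diag(S)).sum() / var_s) if var_s > _EPS else 1.0
    else:
        s = 1.0
    t = mu_t - s * R @ mu_s
    return R, t, s


def point_segment_distance(
    points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """Exact Euclidean distance from each point to the segment [a, b]."""
    p = np.atleast_2d(points).astype(float)
    a = np.asarray(seg_a, dtype=float)
    d = np.asarray(seg_b, dtype=float) - a
    denom = float(d @ d)
    if denom < _EPS:
        return np.linalg.norm(p - a, axis=1)
    u = np.clip((p - a) @ d / denom, 0.0, 1.0)
    proj = a + u[:, None] * d
    return np.linalg.norm(p - proj, axis=1)


def sample_surface(
    vertices: np.ndarray,
    faces: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted uniform surface samples; returns (points, face index)."""
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    fi = rng.choice(len(f), size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    w0 = 1.0 - r1
    w1 = r1 * (1.0 - r2)
    w2 = r1 * r2
    pts = w0[:, None] * v[f[fi, 0]] + w1[:, None] * v[f[fi, 1]] + w2[:, None] * v[f[fi, 2]]
    return pts, fi


def _point_triangle_closest(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on one triangle to one point (Ericson's algorithm)."""
    a, b, c = tri
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3 = ab @ bp
    d4 = ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5 = ab @ cp
    d6 = ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


class MeshProximity:
    """Closest-point queries against a triangle mesh.

    Candidate faces come from a k-d tree over face centroids; the exact
    point-triangle distance is evaluated on the candidates. ``k`` trades
    exactness for speed; with k covering a few rings of faces the result is
    exact for the smooth, well-shaped meshes used here.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 24):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        self.triangles = self.vertices[self.faces]
        self._tree = cKDTree(self.triangles.mean(axis=1))
        self.k = min(k, len(self.faces))

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, face indices)."""
        p = np.atleast_2d(points).astype(float)
        _, cand = self._tree.query(p, k=self.k)
        cand = np.atleast_2d(cand)
        out_pts = np.empty_like(p)
        out_fi = np.empty(len(p), dtype=int)
        out_d = np.empty(len(p))
        for i, (pt, faces_i) in enumerate(zip(p, cand)):
            best_d = np.inf
            for fi in faces_i:
                q = _point_triangle_closest(pt, self.triangles[fi])
                d = np.linalg.norm(q - pt)
                if d < best_d:
                    best_d = d
                    out_pts[i] = q
                    out_fi[i] = fi
            out_d[i] = best_d
        return out_pts, out_d, out_fi


def barycentric_coordinates(point: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of a point assumed to lie on the triangle."""
    a, b, c = tri
    v0 = b - a
    v1 = c - a
    v2 = np.asarray(point, dtype=float) - a
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    denom = d00 * d11 - d01 * d01
    if abs(denom) < _EPS:
        raise ValueError("degenerate triangle")
    w1 = (d11 * d20 - d01 * d21) / denom
    w2 = (d00 * d21 - d01 * d20) / denom
    w = np.array([1.0 - w1 - w2, w1, w2])
    return np.clip(w, 0.0, 1.0) / np.clip(w, 0.0, 1.0).sum()
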