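"""Corresponded statistical shape models of vertebrae.

Model building follows the classical point-distribution-model recipe:
Generalized Procrustes Analysis to remove similarity differences, ICP for
initial rigid correspondence of a template to each population member,
non-rigid Coherent Point Drift to deform the template onto each target, and
PCA on the corresponded shape vectors, optionally refined by alternating
ICP correspondence updates with PCA rebuilds.

A model instance is ``x_i = R (mu_i + W_i c_raw) + t`` per vertex, with the
shape coefficients stored in standardized units (multiples of the per-mode
standard deviation): ``c_raw = c_std * sqrt(lambda)``. The 3 + 3 + k free
parameters (axis-angle rotation, translation, coefficients) are the degrees
of freedom optimized during reconstruction.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import MeshProximity, rotvec_to_matrix, umeyama
from .mesh import LabeledMesh


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class Correspondence:
    source_size: int
    target_size: int
    mapping: np.ndarray  # per-source-vertex index into target
    mean_residual: float  # mm

    def __post_init__(self):
        self.mapping = np.asarray(self.mapping, dtype=int)
        if len(self.mapping) != self.source_size:
            raise ValueError("mapping must have one entry per source vertex")
        if self.mapping.size and (self.mapping.min() < 0 or self.mapping.max() >= self.target_size):
            raise ValueError("mapping index out of range")
        if self.mean_residual < 0:
            raise ValueError("mean_residual must be nonnegative")


@dataclass
class PoseShapeParams:
    """Rigid pose plus standardized shape coefficients — the optimized DoF."""

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))  # axis-angle
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros(0))  # std units
    scale: float = 1.0  # optional global isotropic scale, frozen in optimization
    coeff_bound: float = 3.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        if not (np.isfinite(self.rotation).all() and np.isfinite(self.translation).all()
                and np.isfinite(self.coeffs).all()):
            raise ValueError("parameters must be finite")
        if self.coeffs.size and np.abs(self.coeffs).max() > self.coeff_bound + 1e-9:
            raise ValueError(f"|coeffs| must be <= {self.coeff_bound}")

    @property
    def R(self) -> np.ndarray:
        return rotvec_to_matrix(self.rotation)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.rotation, self.translation, self.coeffs])

    @classmethod
    def from_vector(cls, vec: np.ndarray, scale: float = 1.0,
                    coeff_bound: float = 3.0) -> "PoseShapeParams":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[:3], vec[3:6], vec[6:], scale=scale, coeff_bound=coeff_bound)

    def copy(self) -> "PoseShapeParams":
        return PoseShapeParams(self.rotation.copy(), self.translation.copy(),
                               self.coeffs.copy(), self.scale, self.coeff_bound)


@dataclass
class ShapeModel:
    """Mean shape + orthonormal PCA basis over corresponded vertices."""

    template: LabeledMesh
    mean_shape: np.ndarray  # (3N,), mm
    basis: np.ndarray  # (3N, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), mm^2, nonincreasing
    path_annotations: list = field(default_factory=list)  # PathTemplate entries

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float).ravel()
        self.basis = np.asarray(self.basis, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        n3 = 3 * self.template.n_vertices
        if self.mean_shape.shape != (n3,) or self.basis.shape[0] != n3:
            raise ValueError("mean/basis dimensions must match the template")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be nonnegative")

    @property
    def n_modes(self) -> int:
        return self.basis.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.template.n_vertices

    def zero_params(self) -> PoseShapeParams:
        return PoseShapeParams(coeffs=np.zeros(self.n_modes))

    def mode_sd(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.eigenvalues, 0.0))

    def shape_vector(self, coeffs_std: np.ndarray) -> np.ndarray:
        """Shape in model frame (3N,) for standardized coefficients."""
        c_raw = np.asarray(coeffs_std, dtype=float) * self.mode_sd()
        return self.mean_shape + self.basis @ c_raw

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        from .planning import PathTemplate  # local import avoids a cycle

        path = Path(path)
        buf = io.BytesIO()
        np.savez(
            buf,
            mean_shape=self.mean_shape,
            basis=self.basis,
            eigenvalues=self.eigenvalues,
            vertices=self.template.vertices,
            faces=self.template.faces,
            region_labels=self.template.region_labels,
        )
        meta = {
            "format": "spineplan-ssm",
            "version": 1,
            "landmark_indices": {k: int(v) for k, v in self.template.landmark_indices.items()},
            "pedicle_axes": None if self.template.pedicle_axes is None else
            {s: np.asarray(a).tolist() for s, a in self.template.pedicle_axes.items()},
            "path_annotations": [p.to_dict() for p in self.path_annotations],
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("arrays.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        from .planning import PathTemplate

        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format") != "spineplan-ssm":
                raise ValueError("not a spineplan shape-model archive")
            arr = np.load(io.BytesIO(zf.read("arrays.npz")))
            axes = meta.get("pedicle_axes")
            if axes is not None:
                axes = {s: np.asarray(a, dtype=float) for s, a in axes.items()}
            template = LabeledMesh(
                arr["vertices"], arr["faces"], arr["region_labels"],
                {k: int(v) for k, v in meta["landmark_indices"].items()}, axes,
            )
            paths = [PathTemplate.from_dict(d) for d in meta.get("path_annotations", [])]
            return cls(template, arr["mean_shape"], arr["basis"], arr["eigenvalues"], paths)


# --------------------------------------------------------------------------
# alignment primitives
# --------------------------------------------------------------------------


def _centroid_size(pts: np.ndarray) -> float:
    return float(np.linalg.norm(pts - pts.mean(axis=0)))


def generalized_procrustes(
    point_sets: list[np.ndarray], tol: float = 1e-10, max_iter: int = 200
) -> tuple[list[np.ndarray], list[dict], np.ndarray]:
    """Similarity-align corresponded point sets to their Fréchet mean.

    Each set is centered and scaled to unit centroid size, then rotated to
    the evolving consensus; iteration stops when the consensus mean moves by
    less than ``tol``. Returns (aligned sets, per-set transforms, consensus).
    The transform dict maps the original set to its aligned version:
    ``aligned = s * (x - centroid) @ R.T``.
    """
    if len(point_sets) < 2:
        raise ValueError("GPA needs at least 2 point sets")
    sets = [np.asarray(p, dtype=float) for p in point_sets]
    n = sets[0].shape
    for p in sets:
        if p.shape != n:
            raise ValueError("all point sets must have equal cardinality")
        if not np.isfinite(p).all():
            raise ValueError("point sets must be finite")

    centroids = [p.mean(axis=0) for p in sets]
    sizes = [_centroid_size(p) for p in sets]
    normed = [(p - c) / s for p, c, s in zip(sets, centroids, sizes)]
    rotations = [np.eye(3) for _ in sets]
    aligned = [p.copy() for p in normed]

    mean = aligned[0] / np.linalg.norm(aligned[0])
    converged = False
    for _ in range(max_iter):
        for i, p in enumerate(normed):
            R, _, _ = umeyama(p, mean, with_scale=False)
            rotations[i] = R
            aligned[i] = p @ R.T
        new_mean = np.mean(aligned, axis=0)
        new_mean /= np.linalg.norm(new_mean)
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("GPA did not converge within max_iter; returning last iterate")

    transforms = [
        {"scale": 1.0 / s, "rotation": R, "centroid": c}
        for s, R, c in zip(sizes, rotations, centroids)
    ]
    return aligned, transforms, mean


def icp_correspond(
    template: np.ndarray,
    target: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
    with_scale: bool = False,
) -> tuple[Correspondence, np.ndarray, np.ndarray, float]:
    """Rigid ICP of ``template`` onto ``target`` with nearest-neighbor mapping.

    Returns (correspondence under the final pose, R, t, scale) such that the
    aligned template is ``scale * template @ R.T + t``. Nearest-neighbor ties
    resolve to the lowest target index (cKDTree convention on exact ties is
    deterministic for fixed inputs).
    """
    src = np.asarray(template, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("ICP requires non-empty point sets")
    tree = cKDTree(tgt)
    R = np.eye(3)
    t = tgt.mean(axis=0) - src.mean(axis=0)
    s = 1.0
    prev = np.inf
    for _ in range(max_iter):
        moved = s * src @ R.T + t
        dist, idx = tree.query(moved)
        res = float(dist.mean())
        if prev - res < tol:
            break
        prev = res
        R, t, s = umeyama(src, tgt[idx], with_scale=with_scale)
    moved = s * src @ R.T + t
    dist, idx = tree.query(moved)
    corr = Correspondence(len(src), len(tgt), idx, float(dist.mean()))
    return corr, R, t, s


# --------------------------------------------------------------------------
# non-rigid Coherent Point Drift
# --------------------------------------------------------------------------


class CPDDivergenceError(RuntimeError):
    pass


@dataclass
class DeformationField:
    """Gaussian-kernel displacement field fitted by CPD.

    Displacements are defined in the template's normalized frame; the field
    extends naturally to any query point via the same kernel, which is how a
    deformation fitted on control points is applied to a full-resolution
    template.
    """

    control_points: np.ndarray  # normalized template control points
    weights: np.ndarray  # (M, 3) kernel weights
    beta: float
    y_mean: np.ndarray
    y_scale: float
    x_mean: np.ndarray
    x_scale: float

    def transform(self, points: np.ndarray) -> np.ndarray:
        q = (np.asarray(points, dtype=float) - self.y_mean) / self.y_scale
        G = _gaussian_kernel(q, self.control_points, self.beta)
        out = q + G @ self.weights
        return out * self.x_scale + self.x_mean


def _gaussian_kernel(a: np.ndarray, b: np.ndarray, beta: float) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * beta**2))


def cpd_nonrigid(
    template: np.ndarray,
    target: np.ndarray,
    beta: float = 2.0,
    lam: float = 3.0,
    max_iter: int = 60,
    tol: float = 1e-8,
    outlier_w: float = 0.0,
) -> tuple[np.ndarray, DeformationField, dict]:
    """Non-rigid Coherent Point Drift (Gaussian-mixture EM with a
    motion-coherence prior) deforming ``template`` onto ``target``.

    Both clouds are normalized to zero mean, unit RMS scale before the EM
    iterations (the usual CPD convention, which makes ``beta``/``lam``
    dimensionless defaults transferable across data). Returns the deformed
    template in the target's frame, the fitted displacement field, and a
    diagnostic dict with the (nonincreasing) EM objective trajectory.
    """
    Y0 = np.asarray(template, dtype=float)
    X0 = np.asarray(target, dtype=float)
    if Y0.size == 0 or X0.size == 0:
        raise ValueError("CPD requires non-empty point sets")
    if beta <= 0 or lam <= 0:
        raise ValueError("beta and lambda must be positive")

    y_mean, x_mean = Y0.mean(axis=0), X0.mean(axis=0)
    y_scale = float(np.sqrt(((Y0 - y_mean) ** 2).sum() / len(Y0)))
    x_scale = float(np.sqrt(((X0 - x_mean) ** 2).sum() / len(X0)))
    y_scale = y_scale if y_scale > 0 else 1.0
    x_scale = x_scale if x_scale > 0 else 1.0
    Y = (Y0 - y_mean) / y_scale
    X = (X0 - x_mean) / x_scale
    M, N, D = len(Y), len(X), 3

    G = _gaussian_kernel(Y, Y, beta)
    W = np.zeros((M, D))
    TY = Y.copy()
    sigma2 = ((X[None, :, :] - Y[:, None, :]) ** 2).sum() / (D * M * N)

    objective = []
    for it in range(max_iter):
        # E-step: Gaussian responsibilities with optional uniform outlier mass
        d2 = ((X[None, :, :] - TY[:, None, :]) ** 2).sum(axis=2)
        num = np.exp(-d2 / (2.0 * sigma2))
        c = ((2.0 * np.pi * sigma2) ** (D / 2.0)) * outlier_w * M / ((1.0 - outlier_w) * N) \
            if outlier_w > 0 else 0.0
        den = num.sum(axis=0) + c
        den[den == 0] = np.finfo(float).tiny
        P = num / den
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = P1.sum()

        # M-step: solve (diag(P1) G + lam sigma2 I) W = P X - diag(P1) Y
        A = G * P1[:, None] + lam * sigma2 * np.eye(M)
        B = P @ X - P1[:, None] * Y
        W = np.linalg.solve(A, B)
        TY = Y + G @ W

        xPx = (Pt1 * (X**2).sum(axis=1)).sum()
        yPy = (P1 * (TY**2).sum(axis=1)).sum()
        trPXY = (TY * (P @ X)).sum()
        sigma2_new = (xPx - 2.0 * trPXY + yPy) / (Np * D)
        sigma2 = max(float(sigma2_new), 1e-12)

        q = (xPx - 2 * trPXY + yPy) / (2 * sigma2) + Np * D / 2.0 * np.log(sigma2) \
            + lam / 2.0 * float((W * (G @ W)).sum())
        if not np.isfinite(q):
            raise CPDDivergenceError(f"CPD objective became non-finite at iteration {it}")
        objective.append(q)
        if len(objective) > 1 and abs(objective[-2] - objective[-1]) < tol * (1 + abs(objective[-2])):
            break

    fieldobj = DeformationField(Y.copy(), W, beta, y_mean, y_scale, x_mean, x_scale)
    deformed = TY * x_scale + x_mean
    return deformed, fieldobj, {"objective": np.array(objective), "sigma2": sigma2}


# --------------------------------------------------------------------------
# PCA model building
# --------------------------------------------------------------------------


def build_ssm(
    shapes: np.ndarray | list[np.ndarray],
    k: int = 15,
    template: LabeledMesh | None = None,
    path_annotations: list | None = None,
) -> tuple[ShapeModel, np.ndarray]:
    """PCA point-distribution model from corresponded, aligned shape vectors.

    ``shapes`` is (S, 3N) (or a list of 3N vectors / (N, 3) arrays). Returns
    the model plus the *full* spectrum of sample variances, which callers use
    for variance-explained reporting. ``k`` is reduced (with a warning) when
    it exceeds the available rank S-1.
    """
    mat = np.array([np.asarray(s, dtype=float).ravel() for s in shapes])
    S = len(mat)
    if S < 2:
        raise ValueError("need at least 2 shapes")
    mean = mat.mean(axis=0)
    centered = mat - mean
    rank = min(S - 1, mat.shape[1])
    if k > rank:
        warnings.warn(f"requested {k} modes but rank is {rank}; reducing")
        k = rank
    # SVD of the centered data gives eigenvectors of the sample covariance
    U, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    eigvals_full = sv**2 / (S - 1)
    basis = Vt[:k].T
    eigvals = eigvals_full[:k]
    if template is None:
        n = mat.shape[1] // 3
        template = LabeledMesh(mean.reshape(n, 3), np.zeros((0, 3), dtype=int),
                               np.zeros(n, dtype=int))
    model = ShapeModel(template, mean, basis, eigvals,
                       list(path_annotations or []))
    return model, eigvals_full


def variance_explained(eigenvalues: np.ndarray, full_eigenvalues: np.ndarray) -> np.ndarray:
    """Fraction of total population variance captured by each retained mode."""
    ev = np.asarray(eigenvalues, dtype=float)
    total = float(np.asarray(full_eigenvalues, dtype=float).sum())
    if total <= 0:
        return np.zeros_like(ev)
    return ev / total


def instantiate(model: ShapeModel, params: PoseShapeParams) -> LabeledMesh:
    """Evaluate the model: per vertex ``x_i = s R (mu_i + W_i c_raw) + t``."""
    if params.coeffs.size != model.n_modes:
        raise ValueError("coefficient count does not match the model")
    if params.coeffs.size and np.all(params.coeffs == 0) \
            and np.all(params.rotation == 0) and np.all(params.translation == 0) \
            and params.scale == 1.0:
        verts = model.mean_shape.reshape(-1, 3).copy()  # bit-identical mean
    else:
        shape = model.shape_vector(params.coeffs).reshape(-1, 3)
        verts = params.scale * shape @ params.R.T + params.translation
    t = model.template
    axes = None
    if t.pedicle_axes is not None:
        axes = {s: params.scale * a @ params.R.T + params.translation
                for s, a in t.pedicle_axes.items()}
    return LabeledMesh(verts, t.faces.copy(), t.region_labels.copy(),
                       dict(t.landmark_indices), axes)


def instantiate_vertices(model: ShapeModel, params: PoseShapeParams) -> np.ndarray:
    """Vertices only (cheaper than a full LabeledMesh during optimization)."""
    shape = model.shape_vector(params.coeffs).reshape(-1, 3)
    return params.scale * shape @ params.R.T + params.translation


# --------------------------------------------------------------------------
# model-to-mesh fitting, refinement, annotation propagation
# --------------------------------------------------------------------------


def fit_to_mesh(
    model: ShapeModel,
    mesh: LabeledMesh,
    rounds: int = 8,
    n_surface: int = 4000,
    with_scale: bool = False,
    seed: int = 0,
) -> tuple[PoseShapeParams, float]:
    """Fit pose + coefficients to a raw mesh by alternating least squares.

    Each round matches instance vertices to their nearest sampled surface
    point, then updates the similarity pose (closed-form Procrustes) and the
    shape coefficients (closed-form projection on the orthonormal basis,
    clipped to the +/-3 s.d. bound). Returns the parameters and the final
    mean point-to-surface residual (mm).
    """
    from .geometry import sample_surface

    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(mesh.vertices, mesh.faces, n_surface, rng)
    tree = cKDTree(pts)

    mu = model.mean_shape.reshape(-1, 3)
    sd = model.mode_sd()
    params = model.zero_params()
    # rigid (or similarity) initialization from the mean shape
    _, R, t, s = icp_correspond(mu, pts, with_scale=with_scale)
    from scipy.spatial.transform import Rotation as _Rot
    params = PoseShapeParams(_Rot.from_matrix(R).as_rotvec(), t,
                             np.zeros(model.n_modes), scale=s if with_scale else 1.0)

    residual = np.inf
    for _ in range(max(rounds, 0)):
        verts = instantiate_vertices(model, params)
        dist, idx = tree.query(verts)
        targets = pts[idx]
        residual = float(dist.mean())
        # pose update with the current shape
        shape = model.shape_vector(params.coeffs).reshape(-1, 3)
        R, t, s = umeyama(shape, targets, with_scale=with_scale)
        # coefficient update with the new pose: project residual on the basis
        local = (targets - t) @ R / max(s, 1e-12)
        c_raw = model.basis.T @ (local - mu).ravel()
        c_std = np.clip(np.divide(c_raw, sd, out=np.zeros_like(c_raw), where=sd > 1e-12),
                        -params.coeff_bound, params.coeff_bound)
        params = PoseShapeParams(_Rot.from_matrix(R).as_rotvec(), t, c_std,
                                 scale=s if with_scale else 1.0)
    verts = instantiate_vertices(model, params)
    dist, _ = tree.query(verts)
    return params, float(dist.mean())


def refine_ssm(
    model: ShapeModel,
    raw_meshes: list[LabeledMesh],
    rounds: int = 2,
    k: int | None = None,
    seed: int = 0,
    residual_tol: float = 1e-6,
) -> tuple[ShapeModel, list[float]]:
    """Alternate model-to-mesh fitting, correspondence update and PCA rebuild.

    The mean fitting residual over the population is tracked per round; if a
    round increases it by more than ``residual_tol`` the best previous model
    is returned.
    """
    if rounds <= 0:
        return model, []
    k = k or model.n_modes
    best_model = model
    residuals: list[float] = []
    for r in range(rounds):
        shapes = []
        round_res = []
        for i, mesh in enumerate(raw_meshes):
            params, res = fit_to_mesh(model, mesh, seed=seed + 7 * i)
            round_res.append(res)
            inst = instantiate_vertices(model, params)
            prox = MeshProximity(mesh.vertices, mesh.faces)
            surf_pts, _, _ = prox.closest(inst)
            # map corresponded surface points back into the model frame
            local = (surf_pts - params.translation) @ params.R / max(params.scale, 1e-12)
            shapes.append(local.ravel())
        residuals.append(float(np.mean(round_res)))
        if len(residuals) > 1 and residuals[-1] > residuals[-2] + residual_tol:
            return best_model, residuals
        best_model = model
        model, _ = build_ssm(np.array(shapes), k=k, template=model.template,
                             path_annotations=model.path_annotations)
    return model, residuals


def build_ssm_from_meshes(
    meshes: list[LabeledMesh],
    k: int = 15,
    template_index: int = 0,
    path_endpoints: dict[str, np.ndarray] | None = None,
    cpd_control: int = 500,
    cpd_target: int = 800,
    cpd_beta: float = 2.0,
    cpd_lambda: float = 3.0,
    cpd_max_iter: int = 40,
    refine_rounds: int = 0,
    seed: int = 0,
) -> tuple[ShapeModel, np.ndarray]:
    """Full correspondence-and-PCA pipeline from raw labeled meshes.

    One mesh is the template; for every other mesh the template is rigidly
    ICP-aligned, deformed by non-rigid CPD (fitted on control-point subsets
    and extended to the full template by its Gaussian displacement field) and
    projected onto the target surface, giving a corresponded point set with
    the template's cardinality and ordering. GPA then removes similarity
    differences and PCA yields the model. Because GPA normalizes size, the
    aligned shapes are rescaled by the population's mean centroid size so
    the model lives in millimetres at the average specimen size.

    ``path_endpoints`` (side -> stacked (entry, exit) 3D points in the
    template's original frame) are anchored barycentrically on the template
    and stored as the model's path annotations.

    Returns (model, full eigenvalue spectrum).
    """
    from .planning import annotate_template_paths

    if len(meshes) < 2:
        raise ValueError("need at least 2 meshes")
    tmpl = meshes[template_index]
    shapes = []
    for i, m in enumerate(meshes):
        if i == template_index:
            shapes.append(tmpl.vertices.ravel())
            continue
        _, R, t, s = icp_correspond(tmpl.vertices, m.vertices, with_scale=True)
        moved = s * tmpl.vertices @ R.T + t
        sub = np.unique(np.linspace(0, len(moved) - 1, min(cpd_control, len(moved))).round().astype(int))
        tsub = np.unique(np.linspace(0, len(m.vertices) - 1, min(cpd_target, len(m.vertices))).round().astype(int))
        _, fld, _ = cpd_nonrigid(moved[sub], m.vertices[tsub], beta=cpd_beta,
                                 lam=cpd_lambda, max_iter=cpd_max_iter)
        deformed = fld.transform(moved)
        surf, _, _ = MeshProximity(m.vertices, m.faces).closest(deformed)
        # express the corresponded points in the template's original frame
        shapes.append(((surf - t) @ R / s).ravel())

    aligned, transforms, _ = generalized_procrustes([s.reshape(-1, 3) for s in shapes])
    mean_size = float(np.mean([
        np.linalg.norm(s.reshape(-1, 3) - s.reshape(-1, 3).mean(axis=0)) for s in shapes
    ]))
    shapes_mm = np.array([a.ravel() * mean_size for a in aligned])

    # carry the template's annotations into the model (GPA-aligned) frame
    tr0 = transforms[template_index]
    a0 = tr0["scale"] * mean_size
    R0 = tr0["rotation"]
    t0 = -a0 * R0 @ tr0["centroid"]
    template_model = tmpl.transformed(R0, t0, a0)
    template_model = LabeledMesh(
        shapes_mm[template_index].reshape(-1, 3), tmpl.faces.copy(),
        tmpl.region_labels.copy(), dict(tmpl.landmark_indices),
        template_model.pedicle_axes,
    )

    annotations = []
    if path_endpoints:
        # barycentric anchors are topology-level: anchor on the original
        # template geometry, evaluate on any instance
        annotations = annotate_template_paths(tmpl, path_endpoints)

    model, full_ev = build_ssm(shapes_mm, k=k, template=template_model,
                               path_annotations=annotations)
    if refine_rounds > 0:
        model, _ = refine_ssm(model, meshes, rounds=refine_rounds, seed=seed)
    return model, full_ev


@dataclass
class AnnotationResult:
    """Outcome of atlas-to-mesh annotation transfer with the DICE gate."""

    accepted: bool
    dice: float
    landmark_indices: dict[str, int] | None = None
    path_endpoints: dict[str, np.ndarray] | None = None
    params: PoseShapeParams | None = None


def propagate_annotation(
    model: ShapeModel,
    mesh: LabeledMesh,
    min_dice: float = 0.85,
    voxel_mm: float = 1.0,
    seed: int = 0,
) -> AnnotationResult:
    """Fit the model to a raw mesh and transfer annotations if the fit is
    reliable (volumetric DICE >= ``min_dice``, inclusive).

    Landmarks transfer by nearest raw-mesh vertex to the fitted instance's
    landmark vertices; template path endpoints transfer as 3D points on the
    raw surface.
    """
    from .metrics import dice as dice_fn
    from .planning import propagate_path

    params, _ = fit_to_mesh(model, mesh, seed=seed)
    fitted = instantiate(model, params)
    occ_a, occ_b = voxelize_common(fitted, mesh, voxel_mm)
    score = dice_fn(occ_a, occ_b)
    if score < min_dice:
        return AnnotationResult(False, score, params=params)

    tree = cKDTree(mesh.vertices)
    lmk = {}
    for name, idx in fitted.landmark_indices.items():
        _, j = tree.query(fitted.vertices[idx])
        lmk[name] = int(j)
    endpoints = {}
    for tmpl in model.path_annotations:
        plan = propagate_path(model, params, tmpl)
        endpoints[tmpl.side] = np.vstack([plan.entry, plan.exit])
    return AnnotationResult(True, score, lmk, endpoints, params)


def voxelize_common(mesh_a: LabeledMesh, mesh_b: LabeledMesh, voxel_mm: float = 1.0):
    """Voxelize two meshes on one shared grid (required for volumetric DICE)."""
    from .metrics import voxelize

    lo = np.minimum(mesh_a.vertices.min(axis=0), mesh_b.vertices.min(axis=0))
    hi = np.maximum(mesh_a.vertices.max(axis=0), mesh_b.vertices.max(axis=0))
    occ_a, _ = voxelize(mesh_a, voxel_mm, bounds=(lo, hi))
    occ_b, _ = voxelize(mesh_b, voxel_mm, bounds=(lo, hi))
    return occ_a, occ_b
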