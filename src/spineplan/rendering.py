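"""Differentiable Gaussian-splat rendering of shape-model instances.

Each (possibly subsampled) model vertex is rendered as a 2D Gaussian blob at
its pinhole projection; intensities accumulate additively, mimicking the
integrating nature of radiographic image formation, and the final image is
max-normalized to [0, 1]. For an isotropic world-space splat of standard
deviation sigma_mm the image-plane deviation is sigma_px = sigma_mm * f / z,
which shrinks splats with depth exactly as perspective demands. An optional
anisotropic mode maps a per-vertex 3x3 world covariance through the local
projection Jacobian (cov2d = J Sigma J^T).

The whole map (pose, shape coefficients) -> images is differentiated in
closed form (chain rule through the exponential map, the perspective divide
and the Gaussian footprint). Splats are truncated at ``cutoff_sigmas`` with
the constant tail value subtracted, so the image is continuous in the
parameters and the analytic gradient matches central finite differences to
the contracted tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import BEHIND_EPS, Camera
from .geometry import rotation_matrix_derivatives
from .ssm import PoseShapeParams, ShapeModel


@dataclass
class SplatConfig:
    sigma_mm: float | None = None  # None: mean template edge length at render time
    intensity: float = 1.0
    cutoff_sigmas: float = 4.0
    anisotropic: bool = False
    covariances_mm2: np.ndarray | None = None  # (N, 3, 3), SPD, world frame
    max_splats: int | None = 1500  # deterministic stride subsample of vertices
    normalize: bool = True
    chunk: int = 1024

    def resolve_sigma(self, model: ShapeModel) -> float:
        if self.sigma_mm is not None:
            if self.sigma_mm <= 0:
                raise ValueError("sigma must be positive")
            return float(self.sigma_mm)
        return mean_edge_length(model.template.vertices, model.template.faces)


def mean_edge_length(vertices: np.ndarray, faces: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    if f.size == 0:
        return 1.0
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).mean())


@dataclass
class RenderedView:
    image: np.ndarray  # (H, W) float in [0, 1] when normalized
    camera: Camera
    params: PoseShapeParams | None = None
    raw_max: float = 1.0  # normalization divisor actually applied


def _subsample_indices(n: int, max_splats: int | None) -> np.ndarray:
    if max_splats is None or n <= max_splats:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, max_splats).round().astype(int))


def _normalize(img: np.ndarray) -> tuple[np.ndarray, float]:
    m = float(img.max()) if img.size else 0.0
    if m <= 0:
        warnings.warn("no visible splats; rendered image is zero")
        return img, 1.0
    return img / m, m


def splat_render(
    points2d: np.ndarray,
    depths: np.ndarray,
    camera: Camera,
    config: SplatConfig,
    sigma_mm: float = 1.0,
    covariances_mm2: np.ndarray | None = None,
) -> RenderedView:
    """Render already-projected points as additive Gaussian splats."""
    uv = np.atleast_2d(points2d)
    z = np.asarray(depths, dtype=float)
    vis = z > BEHIND_EPS
    if not vis.any():
        warnings.warn("no visible points; returning zero image")
        return RenderedView(np.zeros((camera.height, camera.width)), camera)
    f_bar = 0.5 * (camera.K[0, 0] + camera.K[1, 1])
    if config.anisotropic and covariances_mm2 is not None:
        img = _splat_aniso(uv[vis], z[vis], covariances_mm2[vis], camera, config)
    else:
        sig_px = sigma_mm * f_bar / z[vis]
        img = _splat_iso_forward(uv[vis], sig_px, camera, config)[0]
    if config.normalize:
        img, m = _normalize(img)
    else:
        m = 1.0
    return RenderedView(img, camera, raw_max=m)


def _splat_iso_forward(uv, sig_px, camera, config, cache=None):
    """Accumulate isotropic truncated Gaussians; optionally cache footprints."""
    H, W = camera.height, camera.width
    img = np.zeros(H * W)
    cut = config.cutoff_sigmas
    tail = np.exp(-0.5 * cut * cut)
    for s in range(0, len(sig_px), config.chunk):
        sl = slice(s, min(s + config.chunk, len(sig_px)))
        u0 = uv[sl, 0]
        v0 = uv[sl, 1]
        sg = sig_px[sl]
        h = int(np.ceil(cut * sg.max()))
        offs = np.arange(-h, h + 1)
        cu = np.round(u0).astype(int)
        cv = np.round(v0).astype(int)
        qu = cu[:, None, None] + offs[None, :, None]  # (n, K, 1)
        qv = cv[:, None, None] + offs[None, None, :]  # (n, 1, K)
        du = qu - u0[:, None, None]
        dv = qv - v0[:, None, None]
        r2 = du * du + dv * dv
        s2 = (sg**2)[:, None, None]
        inside = (r2 <= (cut * sg[:, None, None]) ** 2) \
            & (qu >= 0) & (qu < W) & (qv >= 0) & (qv < H)
        expv = np.exp(-0.5 * r2 / s2) * inside
        g = config.intensity * np.clip(expv - tail * inside, 0.0, None)
        flat = np.clip(qv, 0, H - 1) * W + np.clip(qu, 0, W - 1)
        np.add.at(img, flat.ravel(), g.ravel())
        if cache is not None:
            cache.append((sl, flat, inside, expv, du, dv, sg))
    return img.reshape(H, W), cache


def _splat_aniso(uv, z, covs, camera, config):
    """Forward-only anisotropic splats: cov2d = J Sigma J^T per point."""
    H, W = camera.height, camera.width
    img = np.zeros(H * W)
    cut = config.cutoff_sigmas
    tail = np.exp(-0.5 * cut * cut)
    M = camera.K @ camera.R
    for (u0, v0), zi, S in zip(uv, z, covs):
        J = np.vstack([(M[0] - u0 * M[2]) / zi, (M[1] - v0 * M[2]) / zi])
        C = J @ S @ J.T
        C = 0.5 * (C + C.T) + 1e-9 * np.eye(2)
        evals = np.linalg.eigvalsh(C)
        h = int(np.ceil(cut * np.sqrt(evals.max())))
        Ci = np.linalg.inv(C)
        qu, qv = np.meshgrid(
            np.arange(round(u0) - h, round(u0) + h + 1),
            np.arange(round(v0) - h, round(v0) + h + 1),
            indexing="ij",
        )
        du, dv = qu - u0, qv - v0
        m2 = Ci[0, 0] * du**2 + 2 * Ci[0, 1] * du * dv + Ci[1, 1] * dv**2
        inside = (m2 <= cut * cut) & (qu >= 0) & (qu < W) & (qv >= 0) & (qv < H)
        g = config.intensity * np.clip(np.exp(-0.5 * m2) - tail, 0.0, None) * inside
        flat = np.clip(qv, 0, H - 1) * W + np.clip(qu, 0, W - 1)
        np.add.at(img, flat.ravel(), g.ravel())
    return img.reshape(H, W)


# --------------------------------------------------------------------------
# full pipeline: params -> images (+ exact gradient)
# --------------------------------------------------------------------------


def _instance_and_jacobian(model: ShapeModel, params: PoseShapeParams, idx: np.ndarray):
    """Vertices X (n, 3) at ``idx`` and dX/dp (n, 3, 6 + k).

    X_i = s R (mu_i + W_i (c_std * sd)) + t, differentiated w.r.t. the
    axis-angle vector (exact exponential-map Jacobian), translation and
    standardized coefficients; the global scale s is frozen.
    """
    k = model.n_modes
    sd = model.mode_sd()
    mu = model.mean_shape.reshape(-1, 3)[idx]
    Wb = model.basis.reshape(-1, 3, k)[idx]  # (n, 3, k)
    Y = mu + Wb @ (params.coeffs * sd)
    R = params.R
    s = params.scale
    X = s * Y @ R.T + params.translation

    n = len(idx)
    J = np.zeros((n, 3, 6 + k))
    dR = rotation_matrix_derivatives(params.rotation)  # (3, 3, 3)
    for j in range(3):
        J[:, :, j] = s * Y @ dR[j].T
    J[:, :, 3:6] = np.eye(3)
    RW = np.einsum("ab,nbk->nak", R, Wb)  # (n, 3, k)
    J[:, :, 6:] = s * RW * sd[None, None, :]
    return X, J


def render_instance(
    model: ShapeModel,
    params: PoseShapeParams,
    cameras: list[Camera],
    config: SplatConfig | None = None,
) -> list[RenderedView]:
    """Instantiate, project and splat into every camera."""
    config = config or SplatConfig()
    sigma = config.resolve_sigma(model)
    idx = _subsample_indices(model.n_vertices, config.max_splats)
    X, _ = _instance_and_jacobian(model, params, idx)
    views = []
    for cam in cameras:
        from .camera import project_points

        uv, z, vis = project_points(cam, X)
        cov = None
        if config.anisotropic and config.covariances_mm2 is not None:
            cov = config.covariances_mm2[idx]
        rv = splat_render(uv, z, cam, config, sigma_mm=sigma, covariances_mm2=cov)
        rv.params = params.copy()
        views.append(rv)
    return views


def render_loss_and_grad(
    model: ShapeModel,
    params: PoseShapeParams,
    cameras: list[Camera],
    targets: list[np.ndarray],
    metric,
    config: SplatConfig | None = None,
) -> tuple[float, np.ndarray, list[np.ndarray]]:
    """Similarity loss and its exact gradient w.r.t. the (6 + k) parameters.

    ``metric`` must expose ``value_and_grad(rendered, targets)`` returning the
    scalar loss and dLoss/dImage per view. Rendering here is *not*
    max-normalized: the NCC-style metrics used for registration are invariant
    to positive rescaling, so the loss value and gradient are unchanged while
    the normalization's non-smooth max is kept out of the chain.
    """
    config = config or SplatConfig()
    if config.anisotropic:
        raise NotImplementedError("gradients are provided for isotropic splats")
    sigma = config.resolve_sigma(model)
    idx = _subsample_indices(model.n_vertices, config.max_splats)
    X, J = _instance_and_jacobian(model, params, idx)

    n_par = J.shape[2]
    rendered = []
    view_data = []
    f_bars = []
    for cam in cameras:
        M = cam.K @ cam.R
        bvec = cam.K @ cam.t
        h = M @ X.T + bvec[:, None]
        z = h[2]
        vis = z > BEHIND_EPS
        u = np.where(vis, h[0] / np.where(vis, z, 1.0), np.nan)
        v = np.where(vis, h[1] / np.where(vis, z, 1.0), np.nan)
        f_bar = 0.5 * (cam.K[0, 0] + cam.K[1, 1])
        sig_px = sigma * f_bar / np.where(vis, z, 1.0)
        cache: list = []
        uv = np.column_stack([u[vis], v[vis]])
        img, _ = _splat_iso_forward(uv, sig_px[vis], cam, config, cache)
        rendered.append(img)
        view_data.append((M, z, vis, u, v, sig_px, cache))
        f_bars.append(f_bar)

    loss, dLdI_list = metric.value_and_grad(rendered, targets)
    if not np.isfinite(loss):
        raise FloatingPointError("similarity loss is non-finite")

    grad = np.zeros(n_par)
    for (M, z, vis, u, v, sig_px, cache), dLdI, cam in zip(view_data, dLdI_list, cameras):
        dflat = dLdI.ravel()
        vis_idx = np.nonzero(vis)[0]
        uvis, vvis, zvis, svis = u[vis], v[vis], z[vis], sig_px[vis]
        s_u = np.zeros(len(vis_idx))
        s_v = np.zeros(len(vis_idx))
        s_s = np.zeros(len(vis_idx))
        for sl, flat, inside, expv, du, dv, sg in cache:
            w = dflat[flat] * inside * config.intensity * expv
            s2 = (sg**2)[:, None, None]
            s_u[sl] = (w * du / s2).sum(axis=(1, 2))
            s_v[sl] = (w * dv / s2).sum(axis=(1, 2))
            s_s[sl] = (w * (du * du + dv * dv) / (s2 * sg[:, None, None])).sum(axis=(1, 2))
        # chain to 3D: du0/dX, dv0/dX, dsigma/dX per visible point
        duX = (M[0][None, :] - uvis[:, None] * M[2][None, :]) / zvis[:, None]
        dvX = (M[1][None, :] - vvis[:, None] * M[2][None, :]) / zvis[:, None]
        dsX = -(svis / zvis)[:, None] * M[2][None, :]
        wX = s_u[:, None] * duX + s_v[:, None] * dvX + s_s[:, None] * dsX  # (nvis, 3)
        grad += np.einsum("na,nap->p", wX, J[vis_idx])
    if not np.isfinite(grad).all():
        bad = int(np.nonzero(~np.isfinite(grad))[0][0])
        raise FloatingPointError(f"non-finite gradient in parameter component {bad}")
    return float(loss), grad, rendered


def gradient(
    model: ShapeModel,
    params: PoseShapeParams,
    cameras: list[Camera],
    targets: list[np.ndarray],
    metric,
    config: SplatConfig | None = None,
) -> np.ndarray:
    """Gradient of the multi-view similarity loss w.r.t. all free DoF."""
    _, g, _ = render_loss_and_grad(model, params, cameras, targets, metric, config)
    return g


def finite_difference_gradient(
    model: ShapeModel,
    params: PoseShapeParams,
    cameras: list[Camera],
    targets: list[np.ndarray],
    metric,
    config: SplatConfig | None = None,
    step: float = 1e-3,
) -> np.ndarray:
    """Central finite differences of the same loss; the independent oracle."""
    config = config or SplatConfig()

    def loss_at(vec):
        p = PoseShapeParams.from_vector(vec, scale=params.scale,
                                        coeff_bound=np.inf)
        loss, _, _ = render_loss_and_grad(model, p, cameras, targets, metric, config)
        return loss

    v0 = params.as_vector()
    g = np.zeros_like(v0)
    for i in range(len(v0)):
        vp, vm = v0.copy(), v0.copy()
        vp[i] += step
        vm[i] -= step
        g[i] = (loss_at(vp) - loss_at(vm)) / (2 * step)
    return g


# --------------------------------------------------------------------------
# image I/O (16-bit PNG)
# --------------------------------------------------------------------------


def save_image_png16(image: np.ndarray, path) -> None:
    from PIL import Image

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(path)


def load_image_png16(path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path), dtype=float)
    return arr / 65535.0
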