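"""2D/3D registration: landmark initialization and gradient-based refinement.

Initialization triangulates the anatomical landmarks detected in both views
(requiring at least three in common; a backup set derived from the projected
silhouette's bounding box is the fallback) and solves the closed-form
similarity fit from the model's template landmarks to the triangulated
points. Refinement then minimizes a multi-view image-similarity loss over
the pose and standardized shape coefficients by a staged first-order method
with exact analytic gradients through the splat renderer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .camera import Camera, angular_separation_deg
from .geometry import umeyama
from .mesh import BACKUP_LANDMARK_NAMES, LabeledMesh, LANDMARK_NAMES
from .rendering import SplatConfig, render_loss_and_grad
from .ssm import PoseShapeParams, ShapeModel, instantiate


class DegenerateGeometryError(ValueError):
    pass


class InitializationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# similarity metrics
# --------------------------------------------------------------------------


class NCCMetric:
    """Mean over views of (1 - NCC); NCC is the zero-mean, unit-variance
    inner product over all pixels. Range [0, 2]; invariant to affine
    intensity rescaling of either image; zero gradient at rendered == target.
    """

    name = "ncc"

    def value_and_grad(self, rendered: list[np.ndarray], targets: list[np.ndarray]):
        if len(rendered) != len(targets):
            raise ValueError("one target per rendered view required")
        losses = []
        grads = []
        for r, t in zip(rendered, targets):
            if r.shape != t.shape:
                raise ValueError("rendered/target image shapes differ")
            rc = r - r.mean()
            tc = t - t.mean()
            nr = np.sqrt((rc**2).sum())
            nt = np.sqrt((tc**2).sum())
            if nr <= 0 or nt <= 0:
                warnings.warn("constant image in NCC; contributing loss 1")
                losses.append(1.0)
                grads.append(np.zeros_like(r))
                continue
            ncc = float((rc * tc).sum() / (nr * nt))
            losses.append(1.0 - ncc)
            g = -(tc / (nr * nt) - ncc * rc / (nr * nr))
            grads.append(g)
        n = len(rendered)
        return float(np.mean(losses)), [g / n for g in grads]

    def __call__(self, rendered, targets):
        return self.value_and_grad(rendered, targets)[0]


class SmoothedNCCMetric:
    """NCC on Gaussian-smoothed images (default sigma 4 px, both images).

    The low-pass filter makes the similarity robust to the deliberate splat
    width mismatch between the target simulator and the registration renderer
    (and, on real data, to point-spread differences between image chains);
    plain global NCC acquires a small pose bias under such mismatch. The
    gradient is exact: the adjoint of the symmetric Gaussian filter is the
    same filter.
    """

    name = "ncc-smooth"

    def __init__(self, sigma_px: float = 4.0):
        if sigma_px < 0:
            raise ValueError("sigma must be nonnegative")
        self.sigma_px = float(sigma_px)
        self._base = NCCMetric()

    def _blur(self, img):
        from scipy.ndimage import gaussian_filter

        return gaussian_filter(img, self.sigma_px, mode="constant")

    def value_and_grad(self, rendered, targets):
        if self.sigma_px == 0:
            return self._base.value_and_grad(rendered, targets)
        rs = [self._blur(r) for r in rendered]
        ts = [self._blur(t) for t in targets]
        loss, grads = self._base.value_and_grad(rs, ts)
        return loss, [self._blur(g) for g in grads]

    def __call__(self, rendered, targets):
        return self.value_and_grad(rendered, targets)[0]


class ConstantMetric:
    """Zero-information metric (constant loss); useful as a control."""

    name = "constant"

    def __init__(self, value: float = 1.0):
        self.value = value

    def value_and_grad(self, rendered, targets):
        return self.value, [np.zeros_like(r) for r in rendered]


METRICS = {"ncc": NCCMetric, "ncc-smooth": SmoothedNCCMetric}


def ncc_loss(rendered: list[np.ndarray], targets: list[np.ndarray]) -> float:
    """Multi-view NCC dissimilarity (mean over views of 1 - NCC)."""
    return NCCMetric().value_and_grad(rendered, targets)[0]


# --------------------------------------------------------------------------
# triangulation and initialization
# --------------------------------------------------------------------------


def triangulate(
    det_a: np.ndarray, det_b: np.ndarray, cam_a: Camera, cam_b: Camera,
    min_angle_deg: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Midpoint of the shortest segment between the two back-projected rays.

    Returns (3D point, residual = segment length in mm). Rays closer to
    parallel than ``min_angle_deg`` raise :class:`DegenerateGeometryError`.
    """
    o1, d1 = cam_a.ray(np.asarray(det_a, dtype=float))
    o2, d2 = cam_b.ray(np.asarray(det_b, dtype=float))
    cosang = float(np.clip(abs(d1 @ d2), 0.0, 1.0))
    ang = np.degrees(np.arccos(cosang))
    if ang < min_angle_deg:
        raise DegenerateGeometryError(
            f"rays are near-parallel ({ang:.3f} deg < {min_angle_deg} deg)"
        )
    w = o2 - o1
    a11, a12, a22 = d1 @ d1, d1 @ d2, d2 @ d2
    det = a11 * a22 - a12 * a12
    t1 = (a22 * (w @ d1) - a12 * (w @ d2)) / det
    t2 = (a12 * (w @ d1) - a11 * (w @ d2)) / det
    p1 = o1 + t1 * d1
    p2 = o2 + t2 * d2
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


@dataclass
class InitializationReport:
    landmarks_used: list[str]
    n_common: int
    fallback: bool
    angular_separation_deg: float
    triangulation_residuals_mm: dict[str, float] = field(default_factory=dict)


def _template_backup_points(model: ShapeModel) -> dict[str, np.ndarray]:
    """3D counterparts of the silhouette-derived backup landmarks, taken as
    the mean shape's centroid and axis-extreme vertices in the canonical
    frame (an approximation: the 2D backups are view-dependent)."""
    v = model.mean_shape.reshape(-1, 3)
    return {
        "centroid": v.mean(axis=0),
        "superior": v[v[:, 2].argmax()],
        "inferior": v[v[:, 2].argmin()],
        "left": v[v[:, 0].argmin()],
        "right": v[v[:, 0].argmax()],
    }


def initialize_pose(
    detections: list,
    cameras: list[Camera],
    model: ShapeModel,
    with_scale: bool = False,
    min_separation_warn_deg: float = 15.0,
) -> tuple[PoseShapeParams, InitializationReport]:
    """Pose (coefficients zero) from multi-view landmark detections.

    Uses landmarks present in the first two views; with at least three in
    common they are triangulated and a least-squares similarity transform
    maps the template landmarks onto them. With fewer than three, the five
    backup landmarks are used instead (fallback flag set). Fewer than three
    correspondences even with backups raises :class:`InitializationError`.
    """
    if len(detections) < 2 or len(cameras) < 2:
        raise ValueError("need at least two views")
    da, db = detections[0], detections[1]
    ca, cb = cameras[0], cameras[1]
    sep = angular_separation_deg(ca, cb)
    if sep < min_separation_warn_deg:
        warnings.warn(
            f"view separation {sep:.1f} deg is below {min_separation_warn_deg} deg; "
            "geometry is weakly constrained"
        )

    mean_v = model.mean_shape.reshape(-1, 3)
    anatomical = {
        name: mean_v[model.template.landmark_indices[name]]
        for name in LANDMARK_NAMES
        if name in model.template.landmark_indices
    }
    common = [n for n in anatomical if da.has(n) and db.has(n)]
    fallback = len(common) < 3
    if fallback:
        backups = _template_backup_points(model)
        common = [n for n in BACKUP_LANDMARK_NAMES if da.has(n) and db.has(n)]
        template_pts = {n: backups[n] for n in common}
        # any anatomical landmarks that *are* common still help the fit
        for n in anatomical:
            if da.has(n) and db.has(n):
                common.append(n)
                template_pts[n] = anatomical[n]
    else:
        template_pts = {n: anatomical[n] for n in common}
    if len(common) < 3:
        raise InitializationError(
            f"only {len(common)} common landmarks (including backups); need 3"
        )

    tri = {}
    residuals = {}
    for n in common:
        p, res = triangulate(da.position(n), db.position(n), ca, cb)
        tri[n] = p
        residuals[n] = res
    src = np.array([template_pts[n] for n in common])
    dst = np.array([tri[n] for n in common])
    R, t, s = umeyama(src, dst, with_scale=with_scale)
    params = PoseShapeParams(
        Rotation.from_matrix(R).as_rotvec(), t, np.zeros(model.n_modes), scale=s
    )
    report = InitializationReport(common, len(common), fallback, sep, residuals)
    return params, report


# --------------------------------------------------------------------------
# gradient-based refinement
# --------------------------------------------------------------------------


@dataclass
class OptimizationConfig:
    """Staged first-order optimization settings.

    ``stages`` lists (free-parameter group, iterations); step sizes are per
    parameter group (axis-angle radians, mm, standardized coefficients).
    """

    stages: tuple = (("pose", 150), ("pose+shape", 250))
    lr_rotation: float = 0.01
    lr_translation: float = 0.5
    lr_coeffs: float = 0.05
    tol: float = 1e-6
    patience: int = 20
    coeff_bound: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for _, iters in self.stages:
            if iters <= 0:
                raise ValueError("iterations must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class ReconstructionResult:
    params: PoseShapeParams
    loss_trajectory: np.ndarray
    initialization: InitializationReport | None
    fitted_mesh: LabeledMesh
    improved: bool
    initial_loss: float
    final_loss: float


def optimize(
    model: ShapeModel,
    init: PoseShapeParams,
    targets: list[np.ndarray],
    cameras: list[Camera],
    metric=None,
    config: OptimizationConfig | None = None,
    splat: SplatConfig | None = None,
    init_report: InitializationReport | None = None,
) -> ReconstructionResult:
    """Minimize the multi-view similarity loss over pose (+ shape) by Adam
    with per-group step sizes; returns the best-seen parameters.

    Stage "pose" freezes the shape coefficients; "pose+shape" frees all
    degrees of freedom with the coefficients clamped to the +/-bound box.
    Deterministic for fixed inputs and configuration.
    """
    metric = metric or NCCMetric()
    config = config or OptimizationConfig()
    splat = splat or SplatConfig()
    k = model.n_modes
    vec = init.as_vector().copy()
    lr = np.concatenate([
        np.full(3, config.lr_rotation),
        np.full(3, config.lr_translation),
        np.full(k, config.lr_coeffs),
    ])

    def eval_loss_grad(v):
        p = PoseShapeParams.from_vector(v, scale=init.scale, coeff_bound=np.inf)
        loss, g, _ = render_loss_and_grad(model, p, cameras, targets, metric, splat)
        return loss, g

    loss0, _ = eval_loss_grad(vec)
    if not np.isfinite(loss0):
        raise FloatingPointError("loss non-finite at initialization")
    best_vec = vec.copy()
    best_loss = loss0
    trajectory = [loss0]

    b1, b2, eps = 0.9, 0.999, 1e-8
    for group, iters in config.stages:
        mask = np.ones(6 + k)
        if group == "pose":
            mask[6:] = 0.0
        elif group == "shape":
            mask[:6] = 0.0
        m = np.zeros(6 + k)
        s2 = np.zeros(6 + k)
        since_improve = 0
        best_stage = best_loss
        for it in range(1, iters + 1):
            loss, g = eval_loss_grad(vec)
            trajectory.append(loss)
            if loss < best_loss:
                best_loss = loss
                best_vec = vec.copy()
            if loss < best_stage - config.tol:
                best_stage = loss
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= config.patience:
                    break
            g = g * mask
            m = b1 * m + (1 - b1) * g
            s2 = b2 * s2 + (1 - b2) * g * g
            mh = m / (1 - b1**it)
            sh = s2 / (1 - b2**it)
            vec = vec - lr * mask * mh / (np.sqrt(sh) + eps)
            vec[6:] = np.clip(vec[6:], -config.coeff_bound, config.coeff_bound)

    final = PoseShapeParams.from_vector(best_vec, scale=init.scale,
                                        coeff_bound=config.coeff_bound)
    improved = best_loss <= loss0
    if not improved:
        warnings.warn("optimization did not improve on the initial loss")
    return ReconstructionResult(
        final, np.asarray(trajectory), init_report, instantiate(model, final),
        improved, loss0, best_loss,
    )


def default_schedule(
    coarse_metric=None,
    coarse_config: OptimizationConfig | None = None,
    fine_sigma_px: float | None = 1.0,
    fine_iters: int = 200,
) -> tuple:
    """Coarse-to-fine metric schedule for :func:`optimize_multiscale`.

    The coarse stage (heavily smoothed NCC by default) is robust to the
    splat-width mismatch between target and registration renderers but blurs
    away the fine image structure that identifies the low-variance shape
    modes; the fine stage re-optimizes all degrees of freedom under a lightly
    smoothed loss from inside the correct basin. ``fine_sigma_px=None``
    disables the fine stage (single-scale optimization).
    """
    coarse = (coarse_metric or SmoothedNCCMetric(), coarse_config or OptimizationConfig())
    if fine_sigma_px is None:
        return (coarse,)
    fine_cfg = OptimizationConfig(stages=(("pose+shape", fine_iters),), patience=30)
    return (coarse, (SmoothedNCCMetric(sigma_px=fine_sigma_px), fine_cfg))


def optimize_multiscale(
    model: ShapeModel,
    init: PoseShapeParams,
    targets: list[np.ndarray],
    cameras: list[Camera],
    schedule: tuple | None = None,
    splat: SplatConfig | None = None,
    init_report: InitializationReport | None = None,
) -> ReconstructionResult:
    """Chain :func:`optimize` runs over a (metric, config) schedule.

    Each stage starts from the previous stage's best parameters. Loss values
    are only comparable within a stage (each stage has its own metric):
    ``initial_loss`` is the first stage's, ``final_loss`` the last stage's,
    and the concatenated trajectory switches metric at stage boundaries.
    ``improved`` is true when any stage improved on its own starting loss.
    """
    schedule = schedule or default_schedule()
    if not schedule:
        raise ValueError("schedule must contain at least one stage")
    params = init
    trajectories = []
    first = last = None
    improved = False
    for metric, cfg in schedule:
        with warnings.catch_warnings():
            # later stages start near an optimum; their own non-improvement
            # is expected and not a batch-level failure
            if first is not None:
                warnings.simplefilter("ignore")
            res = optimize(model, params, targets, cameras, metric=metric,
                           config=cfg, splat=splat, init_report=init_report)
        params = res.params
        trajectories.append(res.loss_trajectory)
        improved = improved or res.improved
        if first is None:
            first = res
        last = res
    return ReconstructionResult(
        params, np.concatenate(trajectories), init_report, last.fitted_mesh,
        improved, first.initial_loss, last.final_loss,
    )
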