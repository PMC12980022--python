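# Methods

This note documents the model, the algorithms, the main parameters (with
units, defaults and rationale), and the known limitations of `spineplan`.

## Problem statement

Given two (or more) calibrated X-ray-like views of a vertebra — each view an
intensity image plus a set of 2D anatomical landmark detections — recover the
patient-specific 3D vertebra as an instance of a statistical shape model
(SSM), then propagate two pre-annotated transpedicular needle trajectories
onto the reconstruction and verify that neither trajectory breaches a pedicle
wall. Everything runs without CT: the only 3D prior is the shape model.

The reconstruction state has 21 degrees of freedom by default: 3 rotation
(axis-angle), 3 translation (mm) and 15 standardized shape coefficients
(the packaged demo uses 5 coefficients; see "Mode count" below).
The instance equation is

```
X' = s · R(ω) · (X̄ + Φ diag(√λ) c) + t
```

with orthonormal mode matrix `Φ`, eigenvalues `λ` (so `c` is in standard
deviations), and optional global scale `s` (fixed to 1 during registration).

## Synthetic anatomy

`phantom.generate_vertebra` builds a watertight, labeled vertebra-like mesh
from an analytic signed-distance field (body = superellipsoid, pedicles =
capsules, spinous/transverse processes = capsules, canal = subtracted
cylinder) polygonized by marching cubes. Each vertex carries a region label
(body, left/right pedicle, posterior elements) and ten named anatomical
landmarks plus per-side analytic pedicle axes (entry/exit points) are
exported with the mesh. `sample_population` draws parameter variations
(body size/aspect, pedicle radius and splay, process lengths; 8 generator
parameters) for SSM building.

Pedicle-wall semantics: the pedicle primitive is a capsule, whose spherical
end caps are necessarily crossed by any transpedicular path (that is the
entry). The wall used for breach checking is therefore the *tube* wall:
vertices whose axial parameter falls outside the capsule segment are
relabeled to the nearest other region. With the default pedicle radius
(> 2.5 mm + margin) a centered 5 mm path cannot breach by construction.

Realism limits: the phantom is a smooth CSG-style caricature — no cortical
vs trabecular contrast, no endplate concavity, no neighboring vertebrae or
soft tissue, and its radiographs are splat renderings, not attenuation
integrals. It exists to make geometry and optimization testable, not to
mimic clinical image statistics.

## Statistical shape model

`build_ssm_from_meshes` establishes dense correspondence and runs PCA:

1. per-mesh rigid+scale ICP of the template onto the target;
2. non-rigid coherent point drift (CPD, Gaussian-mixture EM with motion
   coherence regularization; `beta=2`, `lambda=3`, 40 EM iterations) on
   stride subsamples (500 control / 800 target points) — the resulting
   deformation field is then evaluated on the full template;
3. projection of the deformed template onto the exact target surface;
4. generalized Procrustes alignment (similarity) of all corresponded sets,
   rescaled by the mean centroid size so the model frame is metric (mm);
5. PCA; modes are retained up to the requested `k` (rank permitting).

Trajectory annotations are stored as barycentric anchors (face index +
barycentric weights) of the entry and exit point on the template; since all
fitted instances share the template topology, annotation propagation is a
constant-time barycentric evaluation — exactly equivariant under the pose.

Mode count: the demo and the recovery study retain `k=5` modes for a
25-phantom population generated from 8 independent parameters. Tail modes of
such a population carry essentially zero variance; their standardized
coefficients are unidentifiable from images and would make coefficient-RMSE
reporting meaningless. `k` is chosen for identifiability, not accuracy
tuning; the API supports any `k` up to the population rank (15 by default
in the CLI).

## Projective rendering

Views are pinhole cameras (3×4 projection, 128×128 px, 640 px focal length,
600 mm source-isocenter distance by default; anteroposterior + lateral or
randomized orbits with a pairwise separation floor of 15°). The renderer is
a Gaussian splatter: subsampled mesh vertices are projected and each
contributes an isotropic 2D Gaussian with σ equal to the mesh mean edge
length divided by the local depth scale. Images are max-normalized.

Numerical choices:

- **4σ truncation with continuous offset subtraction.** Each splat uses
  `g = exp(-r²/2σ²) − exp(-8)` clipped at the 4σ cutoff, so the image is a
  continuous function of the parameters. A hard 3σ cutoff leaves a ~1.1%
  step at the footprint boundary, which breaks the gradient/finite-
  difference agreement contract at the 1e-3 level.
- **Analytic gradients.** The 21-component gradient of the image loss is
  hand-derived (chain rule through instance synthesis, projection, splat
  and the similarity metric) and verified against central finite differences
  (relative error < 1e-3; < 1e-2 for rotation components, which traverse
  the rotation-matrix derivative).

## Registration

- **Initialization** triangulates landmarks detected in at least two views
  (ray-midpoint method; < 1° ray separation raises a degenerate-geometry
  error) and aligns the model's 3D landmarks to them with a closed-form
  similarity fit. At least 3 common anatomical landmarks are required;
  otherwise five backup landmarks derived from the projected silhouette
  bounding box (centroid, superior, inferior, left, right) are used as a
  coarse fallback.
- **Similarity metric**: normalized cross-correlation (NCC), optionally on
  Gaussian-smoothed images (both rendered and target smoothed with the same
  kernel; the gradient is exact through the smoothing). Plain global NCC is
  biased by the deliberate splat-width mismatch between the target simulator
  and the registration renderer (inverse-crime mitigation), displacing the
  rotation optimum by ~2.5°; symmetric smoothing restores consistency.
- **Optimizer**: Adam (momentum-based first-order) on the 21 parameters with
  per-group step sizes 0.01 (rotation, radians), 0.5 (translation, mm), 0.05
  (coefficients, standard deviations); staged activation (pose first, then
  pose+shape), early stopping on patience, best-seen parameters returned,
  coefficients clipped to ±3 s.d.
- **Coarse-to-fine schedule** (`default_schedule` / `optimize_multiscale`):
  stage 1 under σ=4 px smoothed NCC (pose 150 iters, pose+shape 250), stage
  2 under σ=1 px smoothed NCC (pose+shape 200). The heavy smoothing that
  stabilizes pose also blurs away the image detail identifying the lowest-
  variance shape modes (a displaced optimum, not under-convergence); the
  light-smoothing refinement pass roughly halves the standardized-
  coefficient error while leaving pose accuracy unchanged.

Target images for simulated experiments apply inverse-crime mitigation: the
ground-truth mesh is rendered with a 1.5× wider splat plus 5% multiplicative
speckle and 1% additive read noise, so self-registration is never trivially
exact.

## Path planning and verification

A planned trajectory is a 5 mm-diameter cylinder around the entry→exit
segment. `breach_check` samples the pedicle-wall region area-weighted
(default 10 samples/mm²), computes exact point-to-segment distances, and
flags a breach iff the minimum distance is below 2.5 mm — i.e. exactly when
the cylinder contacts the wall. Bipedicular success requires both sides
planned and breach-free. The triangulation baseline (`geoplan_triangulate`)
reconstructs entry and exit independently per pedicle from per-view 2D
annotations; a missing endpoint in any view fails that pedicle only.

## Evaluation metrics

- **DICE**: solid voxelization (z-column ray-crossing parity on a shared
  grid; the grid origin carries a tiny irrational offset so rays avoid
  triangle edges; requires watertight inputs), then voxel overlap.
- **NSD / HD-95 / MASD**: area-weighted surface samples of each mesh are
  measured against the *exact* opposing surface (closest point on mesh, not
  nearest sample), symmetrized. Identical meshes therefore score exactly
  NSD = 1, HD-95 = 0, MASD = 0, and sampling density only affects how finely
  the integrand is sampled, not the distance values themselves.
- **Pose error**: geodesic rotation angle (deg), Euclidean translation (mm),
  RMSE of standardized coefficients.

## Verification experiments

`spineplan.experiments` packages the seeded studies used by both the test
suite and `scripts/acceptance.py`:

| experiment | checks | typical result |
|---|---|---|
| `run_gradient_check` | analytic vs FD gradients, 5 instances | max rel. err ~1e-4 |
| `run_triangulation_check` | noise-free 3D recovery | ~1e-13 mm |
| `run_planted_subspace_check` | PCA recovers 5 planted modes | 100% variance, principal angles ~4e-8 rad |
| `run_recovery_experiment` | 20-case pose+shape recovery | medians: 1.66° / 0.07 mm / 0.28 coeff RMSE / 0.979 DICE |
| `run_determinism_check` | byte-identical demo CSVs | identical |

All experiments are deterministic under their seeds: per-case seeds are
derived arithmetically from the experiment seed, reports use a fixed column
order and rounded floats, and wall-clock time appears only in the summary
JSON, never in the CSV.

## Limitations

- Landmark detection and image synthesis are simulators, not learned models;
  absolute accuracy numbers characterize the geometry/optimization stack,
  not clinical performance.
- Single-vertebra scenes only; no multi-level disambiguation or occlusion.
- The renderer is a point splatter; it has no ray attenuation, so intensity
  is a density proxy and NCC is the only supported similarity family.
- CPD runs on subsampled clouds for tractability; correspondence quality
  (and hence the SSM) degrades if population variation far exceeds the
  generator's default ranges.
- Global scale is fixed during registration (calibrated cameras assumed).
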