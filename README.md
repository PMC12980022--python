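# spineplan

CT-free 3D vertebral reconstruction and transpedicular path planning from two
calibrated X-ray-like views, built on a statistical shape model (SSM) and a
differentiable Gaussian-splat renderer.

Given two views of a vertebra (intensity images plus 2D anatomical landmark
detections), `spineplan`:

1. **initializes** the pose by triangulating landmarks seen in both views and
   fitting a similarity transform to the model's 3D landmarks (silhouette-
   bounding-box backup landmarks when fewer than 3 anatomical ones survive);
2. **optimizes** 21 degrees of freedom (rotation, translation, shape
   coefficients) by gradient descent on normalized cross-correlation between
   splat-rendered views and the targets, with analytic gradients and a
   coarse-to-fine smoothing schedule;
3. **propagates** two pre-annotated transpedicular trajectories (barycentric
   anchors on the model template) onto the reconstruction; and
4. **verifies** each 5 mm trajectory against the pedicle wall (breach iff
   the axis–wall distance drops below 2.5 mm).

Everything needed to exercise the pipeline is generated on the fly: a
parametric vertebra phantom population, simulated landmark detections, and
noisy target radiographs with inverse-crime mitigation. No external data,
network, or GPU is required. See [docs/methods.md](docs/methods.md) for the
model, algorithms, parameters, and limitations.

## Quick start (CLI)

```bash
# 1. a synthetic case: phantom mesh, two cameras, target images, detections
spineplan generate-case --seed 5 --dropout 0.0 -o case/

# 2. a shape model from a population of labeled meshes
python - <<'EOF'
from spineplan import sample_population
meshes, params = sample_population(8, seed=42)
for i, m in enumerate(meshes):
    m.save(f"pop_{i}.ply")
EOF
cp case/path_endpoints.json endpoints.json
spineplan build-ssm pop_*.ply -k 5 --path-endpoints endpoints.json -o model.zip

# 3. reconstruct, plan, verify, score
spineplan reconstruct --model model.zip --case case/ -o fit.json --mesh-out fit.ply
spineplan plan --model model.zip --params fit.json --truth case/truth.ply -o plans.json
spineplan evaluate --fitted fit.ply --truth case/truth.ply -o metrics.json
```

`spineplan plan` prints, per pedicle, the verdict and the minimum wall
distance, e.g. `left: ok (min wall 4.37 mm)`.

## Quick start (Python)

```python
import numpy as np
from spineplan import (PipelineConfig, build_demo_model, default_schedule,
                       evaluate_reconstruction, instantiate, look_at_camera,
                       make_target_views, optimize_multiscale, simulate_detections,
                       initialize_pose, breach_check, propagate_path)

config = PipelineConfig(population_size=10, n_modes=5, seed=0)
model, _ = build_demo_model(config)                     # SSM + path annotations

truth = model.zero_params()
truth.coeffs[:] = np.clip(np.random.default_rng(1).standard_normal(5), -2, 2)
truth_mesh = instantiate(model, truth)

cams = [look_at_camera(np.zeros(3), az, 0.0) for az in (0.0, 90.0)]  # AP + LAT
targets = make_target_views(truth_mesh, cams, seed=2)   # noisy, wider splat
dets = [simulate_detections(truth_mesh, c, 1.0, 0.1, seed=i) for i, c in enumerate(cams)]

init, report = initialize_pose(dets, cams, model)
result = optimize_multiscale(model, init, targets, cams)

print(evaluate_reconstruction(result.fitted_mesh, truth_mesh).to_dict())
for tmpl in model.path_annotations:
    plan = breach_check(propagate_path(model, result.params, tmpl), truth_mesh)
    print(plan.side, "breach" if plan.breach else "ok", f"{plan.min_wall_distance_mm:.2f} mm")
```

## Batch experiments

```bash
spineplan demo -o out/ --cases 10 --seed 0      # reconstruction + planning batch
spineplan baseline -o out/ --seed 0             # triangulation-only comparison
```

Both write `*_cases.csv` (fixed column order, byte-identical across repeated
runs with the same seed), `*_cases.jsonl` and `*_summary.json` on an
identical schema, so the model-based planner and the two-view triangulation
baseline can be compared case by case.

## Testing and verification

```bash
pytest -q                                   # full suite incl. acceptance tests
python scripts/acceptance.py --seed 0 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per release criterion: analytic
gradients vs finite differences, triangulation exactness, the 20-case
parameter-recovery study, planted-subspace PCA recovery, metric oracles,
planning rules (breach threshold, success truth table, rigid equivariance),
and byte-level demo determinism. `scripts/acceptance.py` recomputes the
headline quantities from scratch and writes them as JSON; representative
values (seed 0, single CPU):

| quantity | value |
|---|---|
| gradient max relative error (rotation / other) | 1.3e-4 / 1.6e-4 |
| triangulation max error | ~1e-13 mm |
| planted-subspace variance captured / max principal angle | 1.0 / 4e-8 rad |
| recovery medians (rot / trans / coeff RMSE / DICE) | 1.66° / 0.07 mm / 0.28 / 0.979 |
| demo reports byte-identical | yes |

## Layout

```
src/spineplan/
  geometry.py      rotations, similarity fits, mesh proximity, sampling
  mesh.py          labeled mesh container (+ PLY round trip)
  phantom.py       parametric vertebra generator + population sampling
  ssm.py           GPA, ICP, CPD, PCA model build/fit/propagation
  camera.py        pinhole cameras, orbits, (de)serialization
  rendering.py     Gaussian splatting + analytic gradients
  registration.py  NCC metrics, triangulation, init, optimization
  planning.py      path templates, propagation, breach check, baseline
  metrics.py       DICE / NSD / HD-95 / MASD / pose error
  simulate.py      detection + target-image simulators
  pipeline.py      demo/baseline batch orchestration
  experiments.py   seeded verification studies
  cli.py           `spineplan` command group
```
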