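# jsmap — 3D joint space mapping from clinical CT

`jsmap` measures **joint space width (JSW)** — the distance between the
opposing outer cortical bone surfaces of a joint — in 3D from routine
clinical CT, at sub-voxel precision. Joint space narrowing is the accepted
structural marker of osteoarthritis progression, but clinical CT blur
(point spread function of roughly 0.9–1.0 mm FWHM at 0.31 × 0.31 × 1.5 mm
voxels) is on the same scale as the joint space itself, so direct edge
detection cannot measure it reliably. `jsmap` removes the blur by
**constrained model-based deconvolution**: along a ray through the joint the
underlying density is modelled as a five-level step profile

```
y0 | y_peak | y_js | y_peak | y3        with edges x0 < x1 < x2 < x3
```

(femoral interior, femoral cortex, joint tissue at a fixed 35 HU, acetabular
cortex, far side), blurred by a Gaussian PSF of unknown per-ray width σ.
The observed profile has the closed form

```
y(t) = y0 + Σᵢ Δyᵢ · Φ((t − xᵢ)/σ),     Φ = standard normal CDF
```

Holding the cortical peak density `y_peak` (estimated once per bone) and the
joint tissue density `y_js` fixed makes the deconvolution stable even when
the gap is narrower than the blur; a bounded trust-region least-squares fit
recovers the edges, and `JSW = x2 − x1`.

The package implements the full measurement chain:

- **`volume_io`** — NIfTI/MetaImage volumes, voxel↔world geometry,
  interpolated line profiles along arbitrary rays
- **`surface`** — bone surface from a binary mask (marching cubes with
  field-gradient normals), opposing-bone projection (~5 mm search), joint
  space patch cutting along a margin polyline, isotropic re-triangulation
  (~4,000 vertices)
- **`jsm_core`** — peak density estimation, the per-vertex deconvolution
  fit, steep-gradient outlier removal, error-weighted smoothing, and the
  femoral/acetabular joint surface meshes
- **`hr_jsm`** — the high-resolution reference method: adaptive
  half-maximum threshold crossings (exact for well-resolved edges), with
  positional/extreme-value outlier filters and no smoothing
- **`registration`** — mutual-information similarity registration of
  volumes; scaled-ICP + 3D thin-plate-spline registration of surfaces;
  nearest-vertex value transfer onto an average template surface
- **`metrics`** — bias/precision, Bland-Altman limits of agreement
  (1.96 × SD), RMSCV = 100 × √(mean CV²), central-95 % trimming, and
  per-vertex 3D agreement maps
- **`phantom`** — synthetic two-bone phantoms (parallel plates,
  ball-and-socket) with partial-volume rendering, anisotropic Gaussian PSF,
  noise, and analytic per-vertex ground-truth JSW

## Worked example

Measure a synthetic ball-and-socket joint with a known uniform 3.0 mm gap:

```python
import numpy as np
from jsmap import (PhantomSpec, generate_volume, mesh_from_mask, cut_patch,
                   retriangulate, estimate_peak_density, run_pipeline,
                   ground_truth_jsw)

spec = PhantomSpec(geometry="ball_socket", femoral_radius=10.0, gap=3.0,
                   cortex_thickness=1.5, spacing=(0.5, 0.5, 0.5),
                   psf=(0.8, 0.8, 0.8), psf_is_fwhm=False, noise_sd=0.0,
                   supersample=2, seed=0)
volume, mask, boundary = generate_volume(spec)

mesh = mesh_from_mask(mask)                     # femoral surface
patch = cut_patch(mesh, boundary, seed_point=np.array([0, 0, 13.0]))
patch = retriangulate(patch, 1000)              # uniform sampling frame
jsw_map = run_pipeline(patch, volume, bone_mesh=mesh)  # measure+clean+smooth

ok = np.isfinite(jsw_map.jsw)
truth = ground_truth_jsw(spec, patch)
print(f"measured {np.median(jsw_map.jsw[ok]):.3f} mm "
      f"(truth {truth[0]:.1f} mm) at {ok.sum()} vertices")
```

which prints

```
measured 3.005 mm (truth 3.0 mm) at 1043 vertices
```

The same chain is available from the shell: `jsmap phantom`, `jsmap patch`,
`jsmap measure`, `jsmap measure-hr`, `jsmap register-volumes`,
`jsmap register-surfaces`, `jsmap average-surface`, `jsmap agree`.

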