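# colliflow

Surface-based depth mapping and hemodynamic-response gradient analysis
for thin midbrain structures — in particular, the rostro-caudal
evolution of event-related BOLD responses across the human superior
colliculus (SC).

## Who this is for

High-resolution fMRI of small brainstem nuclei cannot rely on
volumetric ROI averaging: the SC is a few millimetres thick, curved,
and sits next to structures (periaqueductal gray, aqueduct CSF) whose
signals would contaminate any voxel-box average.  `colliflow`
implements the surface-based alternative: it builds a normalized depth
coordinate between the posterior brainstem roof surface and the
cerebral-aqueduct (CA) interface, averages the BOLD signal along depth
streamlines within the superficial 0.5–2 mm, estimates per-vertex
hemodynamic response functions (HRFs) with bootstrap confidence
intervals, classifies them as positive (pHRF) or negative (nHRF)
responses, and quantifies the rostro-caudal amplitude gradient with
geodesic 1-mm band ROIs and linear regression.

## The model in brief

With `S_T` and `S_CA` the signed distances (positive inside) from the
tectum surface and the CA interface, the normalized depth `w` solves

    w·S_CA + (1 − w)·S_T = 0,   w = S_T / (S_T − S_CA) ∈ [0, 1],

zero on the tectum surface and one at the CA interface.  Streamlines
of ∇w from each surface vertex yield a one-to-one depth
correspondence and a physical thickness map.  Per vertex, 85 task
epochs (17 per run × 5 runs; TR 1.25 s, 26.25-s epochs = 21 TRs) are
depth-averaged, upsampled to 0.1 s, baselined, and bootstrapped
(n = 2000) into a mean response with a 68% CI ≈ ±1 SEM.  The HRF is
pHRF if its 2–14-s peak has CNR > 1 (amplitude over CI half-width),
nHRF if a significant initial negative response precedes it.  Band
ROIs grown geodesically from the strongest rostral cluster (peak
CNR > 3, top 20% amplitude) give the amplitude-versus-distance
regression (OLS slope, Pearson R, p < 0.05).

Because no public dataset accompanies the design, the package ships a
fully synthetic phantom — concentric spheres (10 mm / 7 mm) with two
SC-like patches whose true amplitude runs linearly from +1.5% to
−0.5% — so every stage has a closed-form oracle and the whole pipeline
has a recoverable ground truth.

## Worked example

```python
from colliflow import PhantomConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    phantom=PhantomConfig(voxel_size_mm=1.0, rng_seed=3),
    rng_seed=3, out_dir="out",
)
result = run_pipeline(cfg)
sc = result.summary["sc"]["SC_1"]
print(result.summary["thickness_mm"]["mean"])
print(sc["band_peak_amplitudes"][:5])
print(sc["gradient"]["slope"], sc["gradient"]["pearson_r"],
      sc["gradient"]["p_value"])
```

prints (seed 3):

```
3.061913
[1.180656, 0.814213, 0.601944, 0.394954, 0.178389]
-0.917887562272568 -0.9718941784469193 0.005632339746853027
```

The shell thickness recovers the analytic 3 mm; the seed ROI and the
first bands show the injected amplitude decline (the seed average is
below the 1.5% pole value because the seed spans the top-20% region,
not the pole alone); and the regression of band peak amplitude on
normalized rostro-caudal distance is negative and significant —
the phantom's ground-truth gradient, recovered end to end.  `out/`
contains the surfaces (GIFTI/PLY), depth volumes (NIfTI), thickness
and per-vertex HRF statistics (TSV), band ROIs, ribbon/scatter plots
(SVG) and a machine-readable `summary.json`.

The same pipeline runs from the shell:

```bash
colliflow phantom make --out ph --seed 3 --set voxel_size_mm=1.0
colliflow all run --out out --seed 3 --set phantom.voxel_size_mm=1.0
```

Real-data mode accepts NIfTI BOLD runs and segmentations, an SC vertex
label table, slice offsets and an event design in place of the
phantom; motion correction and registration are assumed done.

## Layout

| module | contents |
| --- | --- |
| `colliflow.phantom` | synthetic dataset: config, event design, HRF kernel, ground truth |
| `colliflow.surface_geometry` | marching-cubes extraction, curvature-flow smoothing, exact signed distances |
| `colliflow.depth_field` | normalized depth `w`, 5-point gradients, streamlines, thickness |
| `colliflow.preprocess` | slice-timing correction, double-RECT drift removal, epoch splitting |
| `colliflow.hrf_analysis` | depth averaging, epoch upsampling, bootstrap CIs, pHRF/nHRF classification |
| `colliflow.roi_gradient` | seed selection, geodesic band dilation, gradient regression |
| `colliflow.pipeline` / `colliflow.cli` | end-to-end orchestration, I/O, `colliflow` command |

See `docs/methods.md` for the full statistical and numerical account.
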