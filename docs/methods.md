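# Methods

`colliflow` analyzes how event-related BOLD hemodynamic response
functions (HRFs) vary across a thin, curved structure — the superior
colliculus (SC) on the midbrain's posterior roof — using a
surface-based depth coordinate system between two nested anatomical
surfaces.  This note records the model, the defaults and the judgment
calls; everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Depth coordinate system

Two closed surfaces bound the tissue of interest: the outer posterior
brainstem roof ("tectum") surface and the inner cerebral-aqueduct (CA)
interface.  Let `S_T(x)` and `S_CA(x)` be the signed Euclidean
distances from a point to each surface, positive for points enclosed
by the surface and negative outside.  The normalized depth `w` solves

    w · S_CA + (1 − w) · S_T = 0   ⟹   w = S_T / (S_T − S_CA),

which is 0 on the tectum surface, 1 at the CA interface, independent
of local thickness, and self-reciprocal (swapping the surfaces maps
`w → 1 − w`).  Distances are exact point-to-triangle (nearest-centroid
k-d-tree candidates with a certified fallback search), signed by
angle-weighted pseudonormals — exact for closed oriented meshes.  The
depth-averaging window downstream is 0.5–2 mm at 0.5–1 mm voxels, so
voxel-resolution distance transforms would be too coarse; that is why
the distance machinery is sub-voxel by construction.

Surfaces come from marching cubes on segmentation volumes (default
iso-level 0.5; both binary masks and partial-volume fractions are
accepted — partial-volume input places vertices with sub-voxel
accuracy, a hard binary mask carries the usual half-voxel staircase
jitter and ~8% area excess, which the curvature-flow refinement
removes).  Refinement is discrete umbrella-operator mean-curvature
flow, default 10 steps at dt = 0.1: enough to remove mask staircase
artifacts while shrinking a 10-mm sphere by ≪ 0.1 mm.

## Streamlines and thickness

`∇w` is computed with 5-point central-difference kernels
(−1, 8, 0, −8, 1)/12h per axis (exact for cubic fields; 3-point and
one-sided stencils at the grid boundary).  From every tectum-surface
vertex a streamline is traced: one step of 0.1 mm along the inward
surface normal, then forward-Euler steps of 0.1 mm along trilinearly
interpolated `∇w` until `w ≥ 1 − ε` (ε = 0.02), the trace leaves the
grid, or a step cap is hit.  Euler integration is adequate because the
field is smooth and the step is ≲ 1/5 voxel; the integrator is
isolated and swappable.  The terminal cumulative arc length,
re-gridded per vertex, is the physical thickness map; traces that fail
to reach the CA produce missing values that propagate (the vertex is
excluded from depth averaging).  Termination by threshold and the
fixed step quantize thickness to roughly ±(ε·thickness + step), about
±0.16 mm on a 3-mm shell.

## Temporal model

The protocol emulated: TR 1.25 s, 26.25-s task epochs (exactly 21
TRs), 17 epochs per run, 5 runs (85 epochs per subject), preceded by a
discarded lead-in (10 TRs; the emulated protocol's 12-s blank is not
an integer TR count, and since the lead-in is discarded only its
approximate length matters).  Preprocessing:

1. **Slice-timing correction** — natural cubic-spline resampling of
   each slice's series from its acquisition grid to the reference grid
   (default reference: start of TR).  Motion correction and anatomical
   registration are out of scope; real-data mode assumes registered
   input and logs a warning.
2. **Drift removal** — the baseline is the series smoothed twice with
   a rectangular moving-average kernel of one epoch duration
   (26.25 s), reflect-padded at the run edges, and subtracted.  For an
   epoch-periodic response this filter removes exactly the epoch mean
   in the run interior; edge distortion is confined to the first/last
   epoch and diluted 17-fold in the epoch average.  Percent-signal-
   change conversion (divide by the voxel's temporal mean, ×100)
   happens here, so all downstream amplitudes are in %; the filtering
   core without the conversion is linear to machine precision
   (`to_percent=False`).
3. **Epoch splitting** — 21-TR epochs cut at the onsets; splitting
   then re-concatenating is lossless.

## Per-vertex HRFs

Voxel timeseries are depth-averaged per vertex: the preprocessed
volume is sampled (trilinear, with precomputed corner weights applied
across all timepoints at once) at streamline points with cumulative
arc length in [0.5, 2.0] mm and averaged uniformly — the superficial
layers, which the emulated experiment drives; vertices thinner than
the window start are dropped.  Each epoch is upsampled to a 0.1-s grid
(cubic spline; interpolation of the default kernel from the TR grid is
accurate to ~0.5% of peak except a ~2.7% transient at t < 2.5 s where
the 1.25-s grid undersamples the onset curvature) and re-referenced so
the mean of its first and last samples is zero.

Bootstrap: 2000 resamples of the 85 epochs with replacement;
timepoint-wise resample means; the mean response is the mean of
resample means and the 68% CI is their 16th–84th percentile band,
numerically the standard error of the mean (measured CI coverage over
1000 simulated datasets: ~67%).  Each vertex gets an independent child
seed spawned from one stage seed, so results are order-independent and
bit-reproducible.

## Classification

The **peak** is the largest mean value 2–14 s after epoch onset; the
**INR** (initial negative response) is the magnitude of the most
negative mean value in its search window.  A feature is significant
when its CNR — amplitude over the 68% CI half-width at that timepoint
(i.e., over one SEM) — exceeds 1.  A window-averaged half-width is
available via `ci_mode="window_mean"`.

Two judgment calls were genuinely open and are both configurable:

- **INR window** (`inr_window_s`, default **[2, 14] s**).  The
  zero-baseline referencing pins the average of the first and last
  fine-grid samples to zero, so the first ~1 s of every epoch contains
  an artificial excursion whose bootstrap CNR behaves like |z| of a
  unit normal — with a window starting at 0 s, roughly a fifth of
  clearly positive vertices acquire a spurious "significant initial
  dip".  A negative hemodynamic response is subject to the same
  vascular delay that motivates starting the peak search at 2 s, so
  the INR search starts there too.
- **Precedence** (`classify_rule`, default **`"inr_precedence"`**): a
  vertex is nHRF when the INR is significant and either no significant
  peak exists or the INR precedes the peak; otherwise pHRF when the
  peak is significant; otherwise unclassified.  The alternative
  (`"peak_first"`: any significant peak wins) misclassifies every
  sign-mirrored negative response in the high-CNR limit, because the
  mirror of the undershoot becomes a significant late positive lobe —
  so it cannot be the intended reading, but it is kept as an option.

## Rostro-caudal gradient

The seed ROI is the connected component, most rostral by centroid
projection, of SC vertices with peak CNR > 3 and peak amplitude in the
top 20% among CNR-passing SC vertices (the reference population for
the percentile is configurable).  Concentric band ROIs of 1-mm width
grow from the seed by flood fill: multi-source Dijkstra over the mesh
edge graph (Euclidean edge weights) restricted to the SC label; band k
collects vertices at geodesic distance [k, k+1) mm; dilation stops at
the first empty band.  Edge-graph geodesics over-estimate true surface
geodesics by at most one edge length on well-tessellated meshes; exact
or heat-method geodesics would be drop-in refinements.

Each ROI's HRF is computed by spatially averaging member vertices per
epoch (85 band-level epochs), then upsampling, bootstrapping and
classifying exactly like a vertex; pooling epochs instead would change
only CI widths, not means.  Peak amplitudes of the pHRF-classified
ROIs (the seed at distance 0, band k at (k + 0.5) mm, rescaled to
[0, 1]) are regressed on normalized distance by ordinary least
squares; the slope's two-sided t-test p-value, Pearson R, and a
significance flag at α = 0.05 are reported.  nHRF and unclassified
bands are excluded; fewer than 3 pHRF ROIs yields a flagged
insufficient-data result instead of a fit.

## The phantom

Geometry is a pair of concentric spheres (outer 10 mm ≙ tectum, inner
7 mm ≙ CA) so every geometric stage has a closed-form oracle:
streamlines are radial, thickness is exactly 3 mm, and `w` is linear
in radius.  Segmentations are written as partial-volume fractions (a
one-voxel linear ramp), which is both what real segmentation
pipelines produce and what places the extracted surface within ~0.01
voxel of the analytic sphere.

Two SC-like patches ("left"/"right") sit on the outer sphere, poles at
±50° from the rostral (+x) axis in the xy-plane — far enough apart
that the default 8-mm patches never overlap.  Within a patch the true
peak amplitude is affine in the great-circle distance from the pole:
1.5% at the pole to −0.5% at 8 mm, crossing zero at 6 mm, so the
caudal end genuinely inverts.  The patch extent is an engineering
choice (the emulated study does not state one); 8 mm spans the extent
of a human SC.

Each in-shell patch voxel carries
`baseline · (1 + amp/100 · r(t) + drift) + noise`, where `r(t)` is the
unit-peak difference-of-gammas kernel (peak at 5.0 s, shallow
undershoot, back to ~0.6% of peak by the epoch end) convolved with the
epoch train, the drift is one cosine (1% of baseline, 300-s period,
run-specific phase) and the noise is i.i.d. Gaussian, default SD 2% of
baseline per voxel.  That noise level follows the calibration target
that the weakest responsive vertices (|amp| = 0.5%) land near
vertex-level CNR 3 after depth averaging over 85 epochs.  What the
phantom deliberately omits: temporally autocorrelated physiological
noise (cardiac/respiratory), motion, distortion, and any laminar
structure within the shell.  Consequently, passing tests demonstrate
the correctness of the geometry, estimation and inference machinery
under the stated noise model — not robustness to structured
physiological noise in real data (where temporal autocorrelation
widens effective CIs and classification is correspondingly harder).

All randomness flows from one integer seed: the phantom seed spawns
per-run noise streams, the pipeline seed spawns per-stage and
per-vertex substreams, so identical configurations reproduce every
output byte for byte.

## Problem sizes used by the tests and acceptance script

The full default resolution (0.5-mm voxels, ~7,500 surface vertices,
~2,200 SC vertices, n_boot = 2000) is used for the geometric oracles
and classification recovery.  The replicate study of the gradient
regression uses the same design at 1-mm voxels (the emulated
acquisition's native resolution) with n_boot = 250 and shared
geometry across 100 noise replicates; the bootstrap-coverage
simulation uses 1000 synthetic vertex datasets of 85 epochs.

## Known limitations

- Euler tracing plus threshold termination biases thickness slightly
  low (≈ −ε·thickness) and quantizes it to the step size.
- Edge-graph geodesics inherit mesh anisotropy; bands can be one edge
  length ragged.
- The percentile bootstrap slightly under-covers at n = 85 (~67% for
  a nominal 68%), a known small-sample property.
- Band amplitudes are means over finite-width annuli of a nonlinear
  (spherical-cap) vertex distribution, so a perfectly linear amplitude
  profile still yields |R| slightly below 1 in the regression.
- Real-data mode expects motion-corrected, registered, single-subject
  input; no group inference is provided.
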