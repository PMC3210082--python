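# Methods

`venoquant` quantifies the visibility of the cerebral venous vasculature on
susceptibility-weighted imaging (SWI) venograms and relates it to Doppler-based
venous-hemodynamic scoring. This note records the models, the numerical
choices, and what the synthetic phantoms do and do not establish.

## SWI reconstruction

Deoxygenated venous blood is paramagnetic; it dephases spins, darkening veins
in gradient-echo magnitude and shifting the local phase. The reconstruction
chain is:

1. **Zero-fill interpolation.** Per-channel, centred in-plane k-space is
   zero-padded to the target matrix and inverse-transformed. Zero-padding does
   not alter the k-space samples (the DC energy is untouched); the image is the
   Dirichlet-kernel interpolation of the coarse reconstruction, scaled so
   values at the original sample positions are preserved. At the default
   geometry (FOV 25.6 × 19.2 cm, 512 × 192 acquired, 768 × 576 target) the
   interpolated in-plane voxel is 0.33 × 0.33 mm. Through-plane zero-filling is
   assumed already done upstream (a scanner-side step); only in-plane padding
   is performed here.
2. **Channel recombination.** Each coil channel carries an arbitrary global
   phase offset. The reference is the low-pass (Gaussian-smoothed complex)
   image of the first usable channel with its own mean phase removed; a
   channel's offset is the argument of its inner product with that reference.
   Channels are scaled to unit RMS and summed coherently. All-zero channels
   are dropped with a warning. The exact recipe used in practice varies by
   site; both the smoothing scale and the procedure are configurable.
3. **Bias correction.** A contract-level stand-in for non-uniformity
   normalisation: the multiplicative field is estimated as a heavy Gaussian
   smooth of the magnitude at a configurable spatial scale (`bias_scale_mm`,
   default 40 mm) and divided out, preserving the global mean to < 1%. A
   volume corrected by an external tool can be passed through unchanged. The
   estimator tracks fields that vary slowly relative to the chosen scale; it
   is boundary-biased within roughly two smoothing lengths of the volume edge
   and is not an iterative sharpening method.
4. **Homodyne phase filtering.** Per slice, the complex image is divided by
   its low-pass version (central k-space weighted by a 2D Hanning window,
   default 192 × 144 — one quarter of the interpolated matrix per axis, taken
   as the low-pass *reference* size). Dividing complex images rather than
   subtracting smoothed phase avoids wrap artifacts. On phantoms this
   suppresses whole-FOV smooth phase to < 0.05 rad while retaining ≈ 77% of a
   −0.8 rad two-voxel venous phase shift.
5. **Phase mask.** m = (π + φ)/π for φ < 0, m = 1 otherwise (negative-phase
   polarity by default; a flag mirrors the ramp for scanners with the opposite
   handedness convention). The mask is raised to the 4th power and multiplied
   onto the bias-corrected magnitude, which strictly deepens venous contrast
   relative to a single multiplication.
6. **Minimum-intensity projection.** A sliding-window minimum over 5 slices
   (10 mm at 2 mm slices), stepping one slice at a time, strings dark vein
   voxels into visible vessels. Output slice count is `n − thickness + 1`.

Phase is everywhere reported in (−π, π]; axes are (x=read, y=phase, z=slice),
0-based; spacings in mm.

## Vein segmentation (multi-scale Hessian line filter)

The volume is intensity-inverted so dark veins become bright ridges, then at
each scale σ the Gaussian-derivative Hessian (σ² normalised, σ in mm converted
per axis so anisotropic voxels are honoured) is eigendecomposed with
eigenvalues sorted by increasing magnitude, ties broken by signed value for
reproducibility. With λc = min(−λ₂, −λ₃) clipped at zero, the likeliness is

    f = exp(−λ₁² / (2 α₁² λc²))   λ₁ ≤ 0, λc > 0
    f = exp(−λ₁² / (2 α₂² λc²))   λ₁ > 0, λc > 0
    f = 0                          λc ≤ 0

with α₁ = 0.5 and α₂ = 2 (the asymmetry forgives positive λ₁, restoring
continuity of fragmented vessels). Six log-spaced scales span 0.2–2 mm; the
multi-scale response is the voxelwise maximum. Responses at the tube axis are
stable to ±20% changes of α₁ (< 10% change on phantoms).

Two forms are provided. The **pure-exponential** form is bounded in [0, 1],
invariant to intensity shifts and positive scalings — but it has no magnitude
term: any voxel with slightly negative λ₂, λ₃ (i.e. noise) can score near 1,
so it cannot be thresholded into a segmentation. The **λc-weighted** form
multiplies f by λc, which peaks near the matching scale and separates vessel
from noise. The pipeline driver therefore thresholds the weighted response,
normalised by its volume maximum, at a phantom-calibrated default of 0.2; the
best-scale map is always derived from the weighted response for the same
reason. The pure form remains the module default for direct use.

Segmentation post-processing: threshold within an externally supplied brain
mask (skull stripping is an input contract, never computed here), remove
26-connected components below `min_component_voxels` (default 5), apply
optional manual add/remove edit masks (overlapping edits are rejected as
ambiguous), and render mask-boundary overlays on the mIP slices for review.

## Diameter classification

The vein mask is upsampled 2× in-plane by nearest-neighbour replication
(0.165 mm upsampled voxels), so one symmetric erosion/dilation changes a
vessel's width by one original voxel (0.33 mm). Round k applies a slice-wise
morphological opening, iterating the structuring element k times, to the mask
surviving round k−1; the residual is labelled class k, and whatever survives
round 4 is labelled 4. Labels therefore partition the upsampled mask exactly:
small residual fragments (below the per-round size filter) are *deferred* to
the next round rather than dropped, so no voxel goes unlabelled while isolated
specks cannot contaminate a thin-vein class.

The structuring element is the 4-connected cross. Its iterates are city-block
balls, which approximate circular cross-sections far better than the 3×3
square (whose corners over-erode disks: a 5-pixel disk would die one round
early); for straight in-plane lines both elements peel exactly one pixel of
width per side per iteration. A width-w (upsampled pixels) line is removed at
the first k with w < 2k + 1, so the effective class edges are 0.33, 0.66 and
0.99 mm, nominally labelled < .3, .3–.6, .6–.9 and > .9 mm. Classification is
strictly 2D slice-wise: through-plane diameter is not estimated, and a
through-plane vein (a disk per slice) is binned by its in-plane footprint.

## VVV metrics

* **ATVV** (apparent total venous volume, ml) — vein-voxel count × voxel
  volume, computed on the upsampled class-map grid with the matching voxel
  volume. "Apparent": mIP projection inflates small-vein visibility, so the
  measure is relative, not absolute.
* **VIF** — ATVV normalised by the intracranial volume (supplied externally,
  e.g. brain-mask voxel volume) to correct for head size.
* **DFV** — per-voxel Euclidean distance (exact anisotropic distance
  transform) to the nearest vein voxel, averaged over the whole brain mask
  (vein voxels included by default; a flag restricts to non-vein voxels).
  Longer mean DFV means sparser local vein density; adding vein voxels can
  only lower the map pointwise. DFV is computed on the native (non-upsampled)
  grid for speed; a flag enables the upsampled grid.

## CCSVI scoring

Five Doppler venous-hemodynamic criteria are assessed per subject. CCSVI
positivity is a *count*: at least 2 fulfilled criteria, regardless of
sub-score weights. VHISS is the sum of the five sub-scores, an ordinal
severity measure spanning 0–16. The per-criterion maxima are a weighting
convention defined outside this package; the shipped default (4, 4, 4, 2, 2)
realises the 0–16 range and is fully overridable in configuration.

## Statistics

Group comparisons are nonparametric throughout, two-sided, judged at a
nominal α = .01 with no formal multiplicity correction (the strict nominal
level stands in for one). Exact small-sample distributions where feasible:
Mann-Whitney exact for both n ≤ 12 without ties, else normal approximation
with tie and continuity correction; Wilcoxon signed-rank with zero
differences dropped, exact for n ≤ 15 with untied |differences|; Fisher's
exact two-sided hypergeometric sum; Spearman with midranks and a full
permutation p for n ≤ 9 (t approximation above). Scan-rescan reliability is
the two-way random-effects absolute-agreement single-measure ICC computed
from ANOVA mean squares — the standard form for scan-rescan designs, recorded
in the output. Simulation checks: null rejection at α = .01 falls within
[0.005, 0.02] over 2000 simulations, and a subject-variance fraction of 0.8
is recovered within ±0.1 at n = 500.

## Synthetic phantoms

`make_tube_volume` renders dark cylinders of known radius and orientation on
a bright, noisy background. Voxel membership uses a partial-volume rule: ≥
50% of a 3×3 in-plane subvoxel grid inside the cylinder, with the z-component
of the separation to the axis clamped by half the slice thickness. The clamp
emulates thick-slice partial volume — a vein anywhere inside a slab darkens
that slice — so in-plane veins of sub-slice radius still have a footprint,
while through-plane tubes are unaffected. Ground truth carries per-tube
labels, analytic cylinder volumes (π r² L), expected diameter classes under
the grid quantum, a brain mask and ICV.

Geometry matters at these voxel sizes. Tubes aligned exactly to the grid
quantize pathologically (a 0.6 mm tube centred on a voxel renders one voxel
wide; its voxelised volume can err by 50%). Slightly oblique tubes dither the
sub-voxel phase: voxelised volume then stays within ~7% of π r² L for
diameters ≥ 0.6 mm, and over a radius sweep of 0.3–1.5 mm the modal assigned
diameter class matches the analytic class throughout. The recovery analyses
therefore use oblique tubes: in-plane tubes for the width classifier (the
slice-wise morphology measures in-plane width), through-plane tubes for
segmentation — an *exactly* in-plane vein becomes a constant-position ribbon
across mIP slabs, has λc ≈ 0, and is correctly rejected by a line filter,
whereas real veins are oblique and trace genuine tubes through the mIP stack.

`make_complex_channels` builds per-channel k-space from the phantom magnitude
with a smooth polynomial background phase field, tube-interior phase shifts,
per-channel constant offsets and complex Gaussian noise. `make_cohort` draws
tidy two-group cohorts whose defaults reproduce the study conditions (59 MS
vs 33 HC; ATVV 66.9 (16.6) vs 82.9 (17.4) ml; mean DFV 1.24 (0.2) vs 1.0
(0.1) mm; per-criterion fulfilment probabilities 0.49 vs 0.16, chosen so the
expected CCSVI-positive rates are ≈ 80% and ≈ 18% and expected VHISS ≈ 5 vs
≈ 1.7). Noise is additive Gaussian on magnitude and complex Gaussian on
channels — enough to exercise thresholding and size filtering; Rician
magnitude statistics, motion, flow artifacts, wrap-around and anatomy-shaped
bias fields are *not* modelled, so phantom recovery bounds what the
implementation does, not how the method behaves on real brains. All
randomness flows through one seeded generator and seeds are mandatory.

Problem sizes in the test and acceptance runs (phantoms of ~64–96 voxels
in-plane, 7–24 slices, single tubes per sweep point) were chosen as the
smallest grids on which the geometric effects above are resolved.

## Known limitations

* The bias-correction contract is a smoothing-based stand-in, not an
  iterative histogram-sharpening method; strong tissue structure biases the
  field estimate near edges.
* The mIP stack is treated as a 3D volume by the line filter; perfectly
  in-plane vessels are structurally invisible to it (see above).
* VHISS sub-score maxima are a configurable convention, not a measurement.
* Absolute venous volume is out of reach by construction (mIP inflation);
  all volumes are "apparent".
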