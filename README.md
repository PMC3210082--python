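# venoquant

Quantification of brain venous vasculature visibility (VVV) on
susceptibility-weighted imaging (SWI) venography, with Doppler-based CCSVI
scoring and the nonparametric statistics used to compare patient groups.

SWI exploits the paramagnetism of deoxygenated venous blood: veins lose
signal and acquire local phase, so a phase-mask-enhanced gradient-echo
volume, minimum-intensity-projected along the slice axis, renders the venous
tree dark on a bright parenchyma. `venoquant` implements the full
quantification chain for such data:

1. **Reconstruction** — in-plane zero-fill interpolation of multi-channel
   k-space, coherent channel recombination, bias-field correction, homodyne
   high-pass phase filtering (Hanning window), negative-phase mask raised to
   the 4th power, sliding minimum-intensity projection (mIP).
2. **Vein segmentation** — a multi-scale Hessian line filter. With
   eigenvalues sorted by magnitude (|λ₁| ≤ |λ₂| ≤ |λ₃|) and
   λc = min(−λ₂, −λ₃), tube likeliness is
   `f = exp(−λ₁² / (2 α² λc²))` with α = α₁ = 0.5 for λ₁ ≤ 0 and
   α = α₂ = 2 for λ₁ > 0, maximised over scales σ ∈ (0.2, 2) mm; the
   output is thresholded inside a brain mask and size-filtered.
3. **Diameter classification** — 2× in-plane upsampling and iterated
   slice-wise morphological opening bins veins into mean-diameter classes
   < .3, .3–.6, .6–.9 and > .9 mm.
4. **VVV metrics** — ATVV (apparent total venous volume, ml, total and per
   class), VIF (ATVV / intracranial volume) and DFV (mean distance from the
   nearest vein, mm).
5. **CCSVI / VHISS** — a subject is CCSVI-positive when ≥ 2 of 5 Doppler
   venous-hemodynamic criteria are fulfilled; VHISS = VHISS1 + … + VHISS5
   is the 0–16 severity score.
6. **Statistics** — Mann-Whitney, Wilcoxon signed-rank, Fisher exact and
   Spearman tests (exact small-sample modes) at a nominal α = .01, and
   two-way random-effects absolute-agreement ICC for scan-rescan designs.

A synthetic-phantom module generates SWI-like volumes containing tubes of
known radius and orientation — plus simulated multi-channel complex data and
whole cohorts with known effect sizes — so every stage is testable without
any scanner data. See `docs/methods.md` for models, parameter choices and
limitations.

## Worked example

Segment a two-tube phantom end to end (radii 0.5 and 0.9 mm, 0.33 mm
in-plane voxels, 2 mm slices, 4 simulated coil channels):

```python
import venoquant as vq
from venoquant.config import PipelineConfig
from venoquant.pipeline import run_pipeline

sp, lz = (0.33, 0.33, 2.0), 30.0
tubes = [
    vq.TubeSpec(start_mm=(8.0, 10.0, 0.0), end_mm=(10.0, 12.0, lz), radius_mm=0.5),
    vq.TubeSpec(start_mm=(20.0, 20.0, 0.0), end_mm=(21.5, 18.0, lz), radius_mm=0.9),
]
truth = vq.make_tube_volume(tubes, (96, 96, 16), sp, background=100.0,
                            noise_sd=2.0, seed=7)
ks = vq.make_complex_channels(truth, n_channels=4,
                              channel_offsets_rad=[0.3, -0.5, 1.0, -1.2],
                              noise_sd=1.0, seed=8)
cfg = PipelineConfig(hanning_window=(24, 24))  # window scaled to the 96x96 matrix
result = run_pipeline(cfg, {"kspace": ks, "brain": truth.brain_mask,
                            "icv_ml": truth.icv_ml}, subject="phantom01")
print(result["report"])
```

prints (abridged):

```
atvv_total_ml: 0.6549   atvv_class1_ml: 0.0207   atvv_class2_ml: 0.4174
atvv_class3_ml: 0.0007  atvv_class4_ml: 0.2162
vif: 0.0204             mean_dfv_mm: 6.690       icv_ml: 32.116
```

The recovered ATVV (0.65 ml) exceeds the analytic tube volume (0.10 ml) by
roughly the mIP projection factor — each vein is smeared across the 5-slice
sliding window — which is why the measure is called *apparent*: it tracks,
but deliberately inflates, true venous volume. The 0.5 mm tube lands in the
.3–.6 mm class and the 0.9 mm tube dominates the top classes; the mean DFV of
6.7 mm reflects how sparse two veins are in this small volume.

The same stages are available as a CLI for NIfTI/CSV workflows:

```sh
venoquant phantom --seed 17 --n-tubes 4 --out work/phantom
venoquant classify --in work/phantom/truth_mask.nii.gz --out work/classes.nii.gz
venoquant score   --in cohort.csv --out summary.csv
venoquant compare --in cohort.csv --metric atvv_total_ml --by group
```

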