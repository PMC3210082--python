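"""Synthetic SWI-venogram phantoms with analytic ground truth.

Emulates what the pipeline consumes at each stage without any acquisition:

* mIP-like magnitude volumes — dark cylinders of known radius and
  orientation on a bright, noisy parenchyma background, voxelised with a
  partial-volume rule (a voxel belongs to a tube when at least half of a
  3x3x3 subvoxel grid falls inside the cylinder), which keeps the voxelised
  tube volume close to the analytic pi r^2 L;
* multi-channel complex k-space with a smooth background phase field,
  vein-localised phase shifts and per-channel constant offsets, to exercise
  the reconstruction end to end;
* whole cohorts with known between-group effects on ATVV/DFV and on the
  venous-hemodynamic sub-scores, to feed the scoring and statistics layers.

All randomness flows through one seeded generator; seeds are required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ccsvi_score import DEFAULT_VHISS_MAXIMA, VhProfile, ccsvi_status, vhiss
from .diameter_classify import analytic_diameter_class
from .swi_recon import ComplexChannelData
from .vein_extract import VeinMask

__all__ = ["TubeSpec", "PhantomTruth", "make_tube_volume", "make_complex_channels", "make_cohort"]


@dataclass
class TubeSpec:
    """A straight cylindrical vein segment in mm coordinates."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float
    intensity_drop: float = 0.8   # fractional signal loss inside the tube
    phase_shift_rad: float = -0.8

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be > 0")
        if np.allclose(self.start_mm, self.end_mm):
            raise ValueError("tube endpoints must be distinct")
        if abs(self.phase_shift_rad) >= np.pi:
            raise ValueError("|phase shift| must be < pi")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end_mm, self.start_mm)))

    @property
    def analytic_volume_ml(self) -> float:
        return float(np.pi * self.radius_mm**2 * self.length_mm / 1000.0)

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm


@dataclass
class PhantomTruth:
    """A phantom volume together with its analytic ground truth."""

    volume: np.ndarray
    vein_mask: VeinMask
    tube_labels: np.ndarray          # 0 background, i = tube index + 1
    brain_mask: np.ndarray
    spacing: tuple[float, float, float]
    tubes: list[TubeSpec]
    analytic_volumes_ml: list[float]
    expected_classes: list[int]
    icv_ml: float
    background: float
    overlapping_tubes: bool = False
    phase_field: np.ndarray | None = None

    def truth_voxel_volume_ml(self, tube_index: int) -> float:
        count = int((self.tube_labels == tube_index + 1).sum())
        return count * float(np.prod(self.spacing)) / 1000.0


def _segment_distance_slab(
    points: np.ndarray, a: np.ndarray, b: np.ndarray, half_slab_mm: float
) -> np.ndarray:
    """Distance from each point (..., 3) to the segment a-b, with the z
    component of the separation reduced by ``half_slab_mm`` (floored at 0).

    The z clamp emulates thick-slice partial-volume: a vein anywhere inside a
    slice slab darkens that slice, so the tube footprint in z is the slab
    containing the axis even when the radius is much smaller than the slice
    thickness. For through-plane tubes the clamp is a no-op.
    """
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    sep = points - (a + t[..., None] * ab)
    sz = np.sign(sep[..., 2]) * np.maximum(np.abs(sep[..., 2]) - half_slab_mm, 0.0)
    return np.sqrt(sep[..., 0] ** 2 + sep[..., 1] ** 2 + sz**2)


def _voxelize_tube(
    shape: tuple[int, int, int], spacing: np.ndarray, tube: TubeSpec, subdiv: int = 3
) -> np.ndarray:
    """Partial-volume tube mask.

    A voxel belongs to the tube when at least half of an in-plane
    subdiv x subdiv subvoxel grid lies within the tube radius of the axis,
    with the slab rule of :func:`_segment_distance_slab` applied in z.
    """
    a = np.asarray(tube.start_mm, dtype=float)
    b = np.asarray(tube.end_mm, dtype=float)
    r = tube.radius_mm
    margin = np.array([r, r, max(r, spacing[2] / 2)])
    lo = np.minimum(a, b) - margin
    hi = np.maximum(a, b) + margin
    i0 = np.maximum(np.floor(lo / spacing).astype(int) - 1, 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 2, shape)
    if np.any(i0 >= i1):
        return np.zeros(shape, dtype=bool)
    grids = np.meshgrid(
        *[np.arange(i0[d], i1[d]) * spacing[d] for d in range(3)], indexing="ij"
    )
    centers = np.stack(grids, axis=-1)
    offsets = (np.arange(subdiv) - (subdiv - 1) / 2) / subdiv
    half_slab = spacing[2] / 2.0
    inside = np.zeros(centers.shape[:-1], dtype=np.int32)
    for ox in offsets:
        for oy in offsets:
            pts = centers + np.array([ox, oy, 0.0]) * spacing
            inside += _segment_distance_slab(pts, a, b, half_slab) <= r
    frac = inside / subdiv**2
    mask = np.zeros(shape, dtype=bool)
    mask[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] = frac >= 0.5
    return mask


def make_tube_volume(
    tubes: list[TubeSpec],
    dims: tuple[int, int, int],
    spacing: tuple[float, float, float],
    background: float = 100.0,
    noise_sd: float = 2.0,
    seed: int | None = None,
) -> PhantomTruth:
    """Render dark tubes of known radius on a noisy bright background.

    Voxels within a tube are darkened by its ``intensity_drop``; Gaussian
    noise of the given SD is added everywhere. Deterministic given ``seed``
    (mandatory). Tubes that do not fit inside the volume are rejected;
    overlapping tubes are allowed but flagged.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    sp = np.asarray(spacing, dtype=float)
    extent = (np.asarray(dims) - 1) * sp
    for t in tubes:
        for p in (t.start_mm, t.end_mm):
            if np.any(np.asarray(p) < -1e-9) or np.any(np.asarray(p) > extent + 1e-9):
                raise ValueError(f"tube endpoint {p} outside the volume extent {tuple(extent)}")

    rng = np.random.default_rng(seed)
    labels = np.zeros(dims, dtype=np.int32)
    mask = np.zeros(dims, dtype=bool)
    overlap = False
    volume = np.full(dims, float(background))
    for i, t in enumerate(tubes):
        m = _voxelize_tube(dims, sp, t)
        if np.any(m & mask):
            overlap = True
        labels[m] = i + 1
        mask |= m
        volume[m] = background * (1.0 - t.intensity_drop)
    if overlap:
        warnings.warn("phantom tubes overlap", stacklevel=2)
    volume = volume + rng.normal(0.0, noise_sd, size=dims)

    brain = np.ones(dims, dtype=bool)
    phase = np.zeros(dims)
    for i, t in enumerate(tubes):
        phase[labels == i + 1] = t.phase_shift_rad
    return PhantomTruth(
        volume=volume,
        vein_mask=VeinMask(mask, spacing=tuple(spacing), provenance={"source": "phantom-truth"}),
        tube_labels=labels,
        brain_mask=brain,
        spacing=tuple(spacing),
        tubes=list(tubes),
        analytic_volumes_ml=[t.analytic_volume_ml for t in tubes],
        expected_classes=[analytic_diameter_class(t.diameter_mm, sp[0] / 2.0) for t in tubes],
        icv_ml=float(brain.sum() * np.prod(sp) / 1000.0),
        background=float(background),
        overlapping_tubes=overlap,
        phase_field=phase,
    )


def make_complex_channels(
    truth: PhantomTruth,
    n_channels: int = 1,
    channel_offsets_rad: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    background_phase_amp_rad: float = 1.0,
) -> ComplexChannelData:
    """Simulated multi-channel k-space for a phantom.

    The complex image per channel is the phantom magnitude times
    exp(i * (smooth background field + tube phase shifts + channel offset)),
    plus complex Gaussian noise; the stored data are its centred in-plane
    Fourier samples, ready for :func:`venoquant.swi_recon.zero_fill_reconstruct`.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_channels < 1:
        raise ValueError("need n_channels >= 1")
    offsets = channel_offsets_rad if channel_offsets_rad is not None else [0.0] * n_channels
    if len(offsets) != n_channels:
        raise ValueError("one phase offset per channel required")

    rng = np.random.default_rng(seed)
    nx, ny, nz = truth.volume.shape
    x, y, _ = np.meshgrid(
        np.linspace(0, 1, nx), np.linspace(0, 1, ny), np.arange(nz), indexing="ij"
    )
    background_field = background_phase_amp_rad * (0.6 * x + 0.4 * y**2 - 0.5)
    phase = background_field + (truth.phase_field if truth.phase_field is not None else 0.0)

    mag = np.clip(truth.volume, 0.0, None)
    channels = np.empty((n_channels, nx, ny, nz), dtype=complex)
    for c in range(n_channels):
        img = mag * np.exp(1j * (phase + offsets[c]))
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, img.shape) + 1j * rng.normal(0, noise_sd, img.shape)
        channels[c] = np.fft.fftshift(np.fft.fft2(img, axes=(0, 1)), axes=(0, 1))
    sp = truth.spacing
    return ComplexChannelData(
        channels=channels,
        matrix=(nx, ny),
        fov_cm=(nx * sp[0] / 10.0, ny * sp[1] / 10.0),
        slice_thickness_mm=sp[2],
    )


# --- cohort-level generation -------------------------------------------------

# Defaults reproduce the study conditions: 59 MS vs 33 HC; ATVV ~ 66.9 (16.6)
# vs 82.9 (17.4) ml; mean DFV 1.24 (0.2) vs 1.0 (0.1) mm; per-criterion
# fulfilment probabilities chosen so the expected CCSVI-positive rates are
# about 80% (MS) and 18% (HC).
COHORT_DEFAULTS = {
    "MS": {"n": 59, "atvv": (66.9, 16.6), "dfv": (1.24, 0.2), "p_criterion": 0.49},
    "HC": {"n": 33, "atvv": (82.9, 17.4), "dfv": (1.0, 0.1), "p_criterion": 0.16},
}


def _draw_profile(rng: np.random.Generator, p_criterion: float) -> VhProfile:
    maxima = DEFAULT_VHISS_MAXIMA
    fulfilled = rng.random(len(maxima)) < p_criterion
    subs = [int(rng.integers(1, m + 1)) if f else 0 for f, m in zip(fulfilled, maxima)]
    return VhProfile(subscores=tuple(subs), fulfilled=tuple(bool(f) for f in fulfilled))


def make_cohort(
    n_per_group: dict[str, int] | None = None,
    atvv_shift_ml: float | None = None,
    dfv_shift_mm: float | None = None,
    seed: int | None = None,
    group_params: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, VhProfile]]:
    """Draw a tidy two-group cohort with known effect directions.

    Per subject: ATVV and mean DFV from group-specific normal distributions
    (truncated at zero), and a VH profile with group-specific criterion
    fulfilment probability. ``atvv_shift_ml`` / ``dfv_shift_mm`` override the
    default MS-vs-HC mean differences (0 gives a null cohort with identical
    group distributions). Returns the tidy table and the per-subject
    profiles; the true effect directions live in the generating parameters.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    params = {g: dict(v) for g, v in (group_params or COHORT_DEFAULTS).items()}
    if n_per_group:
        for g, n in n_per_group.items():
            params[g]["n"] = n
    for g, v in params.items():
        if v["n"] < 3:
            raise ValueError("need n >= 3 per group")
    if atvv_shift_ml is not None and "MS" in params and "HC" in params:
        base = params["HC"]["atvv"]
        params["MS"]["atvv"] = (base[0] - atvv_shift_ml, base[1])
    if dfv_shift_mm is not None and "MS" in params and "HC" in params:
        base = params["HC"]["dfv"]
        params["MS"]["dfv"] = (base[0] + dfv_shift_mm, base[1])

    rng = np.random.default_rng(seed)
    rows = []
    profiles: dict[str, VhProfile] = {}
    for g, v in params.items():
        for i in range(v["n"]):
            sid = f"{g}{i:03d}"
            prof = _draw_profile(rng, v["p_criterion"])
            profiles[sid] = prof
            row = {
                "subject": sid,
                "group": g,
                "condition": "pre",
                "atvv_total_ml": max(0.0, rng.normal(*v["atvv"])),
                "mean_dfv_mm": max(0.0, rng.normal(*v["dfv"])),
                "vhiss": vhiss(prof),
                "ccsvi_positive": ccsvi_status(prof),
            }
            for j in range(5):
                row[f"vhiss{j + 1}"] = prof.subscores[j]
                row[f"fulfilled{j + 1}"] = prof.fulfilled[j]
            rows.append(row)
    return pd.DataFrame(rows), profiles
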