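"""Susceptibility-weighted image (SWI) reconstruction.

Turns multi-channel complex gradient-echo data into a venogram: in-plane
zero-fill interpolation of k-space, coherent channel recombination, bias-field
correction of the magnitude, homodyne high-pass filtering of the phase, a
negative-phase mask multiplied repeatedly onto the magnitude, and a sliding
minimum-intensity projection (mIP) along the slice axis.

Conventions: axis order is (x=read, y=phase, z=slice), coordinates are
0-based, spacings are in mm, and phase is reported in the half-open interval
(-pi, pi].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger("venoquant")

__all__ = [
    "ComplexChannelData",
    "SwiVolume",
    "MipStack",
    "zero_fill_reconstruct",
    "recombine_channels",
    "correct_bias",
    "highpass_phase",
    "phase_mask",
    "apply_mask",
    "min_intensity_projection",
]


@dataclass
class ComplexChannelData:
    """Per-channel complex k-space volumes on a common grid.

    ``channels`` has shape (n_channels, nx, ny, nz) with the zero-frequency
    sample at index ``n // 2`` of each in-plane axis (centred k-space).
    The slice axis is assumed already interpolated by the scanner; this
    package only zero-fills in-plane.
    """

    channels: np.ndarray
    matrix: tuple[int, int]          # acquisition matrix (read, phase)
    fov_cm: tuple[float, float]      # field of view (read, phase), cm
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=complex)
        if self.channels.ndim != 4:
            raise ValueError("channels must be (n_channels, nx, ny, nz)")
        if min(self.matrix) <= 0 or min(self.fov_cm) <= 0:
            raise ValueError("matrix and FOV must be strictly positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be > 0")
        if self.channels.shape[1:3] != tuple(self.matrix):
            raise ValueError("channel grid does not match acquisition matrix")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


@dataclass
class SwiVolume:
    """Reconstructed susceptibility-weighted volume (non-negative)."""

    data: np.ndarray
    spacing: tuple[float, float, float]  # mm per axis (x, y, z)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("SWI intensities must be >= 0")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class MipStack:
    """Sliding-window minimum projection along the slice axis."""

    data: np.ndarray
    thickness: int
    step: int
    spacing: tuple[float, float, float]


def _inplane_voxel_mm(fov_cm: tuple[float, float], matrix: tuple[int, int]) -> tuple[float, float]:
    return (10.0 * fov_cm[0] / matrix[0], 10.0 * fov_cm[1] / matrix[1])


def zero_fill_reconstruct(
    kspace: ComplexChannelData, target_matrix: tuple[int, int]
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Zero-fill centred in-plane k-space to ``target_matrix`` and invert.

    Returns per-channel complex image volumes of shape
    (n_channels, tx, ty, nz) together with the interpolated voxel spacing.
    Images are scaled so that values on the coarse grid are preserved
    (sinc/Dirichlet interpolation); the k-space sample sum (DC energy) is
    untouched by the padding.
    """
    nx, ny = kspace.matrix
    tx, ty = int(target_matrix[0]), int(target_matrix[1])
    if tx < nx or ty < ny:
        raise ValueError(f"target matrix {target_matrix} smaller than acquisition {kspace.matrix}")

    nz = kspace.channels.shape[3]
    out = np.zeros((kspace.n_channels, tx, ty, nz), dtype=complex)
    # centred padding: original frequency f sits at index f + n//2
    x0 = tx // 2 - nx // 2
    y0 = ty // 2 - ny // 2
    scale = (tx * ty) / (nx * ny)
    for c in range(kspace.n_channels):
        padded = np.zeros((tx, ty, nz), dtype=complex)
        padded[x0 : x0 + nx, y0 : y0 + ny, :] = kspace.channels[c]
        img = np.fft.ifft2(np.fft.ifftshift(padded, axes=(0, 1)), axes=(0, 1))
        out[c] = img * scale
    dx, dy = _inplane_voxel_mm(kspace.fov_cm, (tx, ty))
    return out, (dx, dy, kspace.slice_thickness_mm)


def _smooth_complex(vol: np.ndarray, sigma: float | tuple) -> np.ndarray:
    return ndimage.gaussian_filter(vol.real, sigma) + 1j * ndimage.gaussian_filter(vol.imag, sigma)


def recombine_channels(
    channel_images: np.ndarray, lowpass_sigma: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Re-centre, normalise and coherently sum channel images.

    Each channel's global phase offset is estimated from its low-frequency
    content: the reference is the low-pass of the first usable channel with
    its own mean phase removed, and a channel's offset is the argument of its
    inner product with that reference. Channels are scaled to unit RMS before
    summation. Returns ``(magnitude, phase)`` with phase in (-pi, pi].
    """
    imgs = np.asarray(channel_images, dtype=complex)
    if imgs.ndim == 3:
        imgs = imgs[None]
    if imgs.shape[0] < 1:
        raise ValueError("need at least one channel")

    # cap the smoothing scale for small test grids
    sig = [min(lowpass_sigma, max(1.0, s / 4)) for s in imgs.shape[1:]]

    usable = [c for c in range(imgs.shape[0]) if np.any(imgs[c] != 0)]
    if not usable:
        raise ValueError("all channels are zero")
    for c in range(imgs.shape[0]):
        if c not in usable:
            log.warning("channel %d is all-zero; excluded from recombination", c)

    ref_lp = _smooth_complex(imgs[usable[0]], sig)
    ref_lp = ref_lp * np.exp(-1j * np.angle(ref_lp.sum()))

    combined = np.zeros(imgs.shape[1:], dtype=complex)
    for c in usable:
        offset = np.angle(np.vdot(ref_lp, imgs[c]))  # vdot conjugates ref
        rms = np.sqrt(np.mean(np.abs(imgs[c]) ** 2))
        combined += imgs[c] * np.exp(-1j * offset) / rms
    combined /= len(usable)

    magnitude = np.abs(combined)
    phase = _wrap_phase(np.angle(combined))
    return magnitude, phase


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Map angles into the half-open interval (-pi, pi]."""
    out = np.asarray(phi, dtype=float).copy()
    out[out <= -np.pi] += 2 * np.pi
    return out


def correct_bias(
    magnitude: np.ndarray,
    scale_mm: float = 40.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    external: np.ndarray | None = None,
) -> np.ndarray:
    """Remove a slowly varying multiplicative intensity field.

    Contract-level stand-in for non-parametric non-uniformity normalisation:
    the field is estimated as a heavy Gaussian smooth (FWHM-like scale
    ``scale_mm``) of the magnitude and divided out; the global mean intensity
    is preserved. When ``external`` is given (a volume corrected by an outside
    tool), it is passed through unchanged.
    """
    mag = np.asarray(magnitude, dtype=float)
    if np.any(mag < 0):
        raise ValueError("magnitude must be non-negative")
    if external is not None:
        return np.asarray(external, dtype=float)
    mean = mag.mean()
    if mean == 0:
        return mag.copy()
    sigma = [max(1.0, scale_mm / s) for s in spacing]
    sigma = [min(sg, max(1.0, dim / 2)) for sg, dim in zip(sigma, mag.shape)]
    fld = ndimage.gaussian_filter(mag, sigma, mode="reflect")
    fld = np.maximum(fld, 1e-12 * mean)
    out = mag / fld
    out *= mean / out.mean()
    return out


def _hanning_window_2d(shape: tuple[int, int], window: tuple[int, int]) -> np.ndarray:
    """A centred 2D Hanning window of the given size embedded in ``shape``."""
    wx, wy = int(window[0]), int(window[1])
    if wx < 2 or wy < 2:
        raise ValueError("window dimensions must be >= 2")
    if wx > shape[0] or wy > shape[1]:
        raise ValueError(f"window {window} exceeds image matrix {shape}")
    w2 = np.outer(np.hanning(wx), np.hanning(wy))
    out = np.zeros(shape)
    x0 = shape[0] // 2 - wx // 2
    y0 = shape[1] // 2 - wy // 2
    out[x0 : x0 + wx, y0 : y0 + wy] = w2
    return out


def highpass_phase(
    cplx: np.ndarray, window: tuple[int, int] = (192, 144)
) -> np.ndarray:
    """Homodyne high-pass filter the phase of a complex volume.

    Per slice, the central k-space weighted by a 2D Hanning window of size
    ``window`` gives a low-pass reference image; the filtered phase is the
    argument of the complex image divided by that reference, which removes
    large-scale field-inhomogeneity phase while keeping local (venous) phase.
    """
    vol = np.asarray(cplx, dtype=complex)
    if vol.ndim == 2:
        vol = vol[..., None]
    win = _hanning_window_2d(vol.shape[:2], window)
    phase = np.empty(vol.shape, dtype=float)
    for z in range(vol.shape[2]):
        k = np.fft.fftshift(np.fft.fft2(vol[:, :, z]))
        lp = np.fft.ifft2(np.fft.ifftshift(k * win))
        phase[:, :, z] = np.angle(vol[:, :, z] * np.conj(lp))
    return _wrap_phase(phase)


def phase_mask(phase: np.ndarray, polarity: str = "negative") -> np.ndarray:
    """Linear phase mask in [0, 1].

    Negative polarity (default, paramagnetic veins with negative filtered
    phase): m = (pi + phi) / pi for phi < 0 and m = 1 for phi >= 0. Positive
    polarity mirrors the ramp onto positive phase. Inputs are re-wrapped into
    (-pi, pi] and the result clipped to [0, 1].
    """
    phi = _wrap_phase(np.angle(np.exp(1j * np.asarray(phase, dtype=float))))
    if polarity == "positive":
        phi = _wrap_phase(-phi)
    elif polarity != "negative":
        raise ValueError("polarity must be 'negative' or 'positive'")
    mask = np.where(phi >= 0, 1.0, (np.pi + phi) / np.pi)
    return np.clip(mask, 0.0, 1.0)


def apply_mask(
    magnitude: np.ndarray,
    mask: np.ndarray,
    n: int = 4,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    provenance: dict | None = None,
) -> SwiVolume:
    """Multiply the phase mask ``n`` times onto the magnitude image."""
    mag = np.asarray(magnitude, dtype=float)
    msk = np.asarray(mask, dtype=float)
    if mag.shape != msk.shape:
        raise ValueError(f"grid mismatch: magnitude {mag.shape} vs mask {msk.shape}")
    if n < 1:
        raise ValueError("mask power n must be >= 1")
    if msk.min() < 0 or msk.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    prov = dict(provenance or {})
    prov.update({"mask_power": int(n)})
    return SwiVolume(data=mag * msk**n, spacing=spacing, provenance=prov)


def min_intensity_projection(swi: SwiVolume, thickness: int = 5, step: int = 1) -> MipStack:
    """Sliding minimum along the slice axis.

    Output slice ``s`` is the voxelwise minimum of input slices
    ``[s, s + thickness)``; with step 1 the output has
    ``n_slices - thickness + 1`` slices.
    """
    if thickness < 1:
        raise ValueError("mIP thickness must be >= 1")
    data = swi.data
    nz = data.shape[2]
    if thickness > nz:
        raise ValueError(f"mIP thickness {thickness} exceeds slice count {nz}")
    if step < 1:
        raise ValueError("mIP step must be >= 1")
    windows = np.lib.stride_tricks.sliding_window_view(data, thickness, axis=2)
    mip = windows.min(axis=-1)[:, :, ::step]
    return MipStack(data=np.ascontiguousarray(mip), thickness=thickness, step=step, spacing=swi.spacing)
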