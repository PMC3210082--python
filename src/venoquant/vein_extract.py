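"""Binary vein-mask extraction from vesselness maps.

Thresholds the line filter output inside the brain, drops small connected
components (26-connectivity) that are noise rather than vessel, applies
optional manual add/remove edits, and renders QC overlays of the mask
boundary on the mIP slices. Skull stripping is an input contract: the brain
mask comes from an external brain-extraction step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .swi_recon import MipStack

__all__ = ["VeinMask", "threshold_vesselness", "size_filter", "apply_manual_edits", "qc_overlay"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VeinMask:
    """Binary vein-voxel map on the mIP grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def threshold_vesselness(
    vesselness: np.ndarray,
    threshold: float,
    brain: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VeinMask:
    """mask = (vesselness >= threshold) AND brain."""
    v = np.asarray(vesselness, dtype=float)
    b = np.asarray(brain, dtype=bool)
    if v.shape != b.shape:
        raise ValueError("vesselness and brain mask grids differ")
    if not b.any():
        raise ValueError("brain mask is empty")
    return VeinMask(
        data=(v >= threshold) & b,
        spacing=spacing,
        provenance={"threshold": float(threshold)},
    )


def size_filter(mask: VeinMask, min_voxels: int) -> VeinMask:
    """Remove 26-connected components smaller than ``min_voxels``."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    data = mask.data
    if min_voxels == 1 or not data.any():
        out = data.copy()
    else:
        labels, n = ndimage.label(data, structure=_STRUCT_26)
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_voxels
            keep[0] = False
            out = keep[labels]
        else:
            out = data.copy()
    prov = dict(mask.provenance)
    prov["size_filter_min_voxels"] = int(min_voxels)
    return VeinMask(data=out, spacing=mask.spacing, provenance=prov)


def apply_manual_edits(mask: VeinMask, add: np.ndarray, remove: np.ndarray) -> VeinMask:
    """(mask | add) & ~remove, with the edit counts recorded."""
    add = np.asarray(add, dtype=bool)
    remove = np.asarray(remove, dtype=bool)
    if add.shape != mask.data.shape or remove.shape != mask.data.shape:
        raise ValueError("edit masks must match the vein mask grid")
    if np.any(add & remove):
        raise ValueError("ambiguous edit: add and remove masks overlap")
    out = (mask.data | add) & ~remove
    prov = dict(mask.provenance)
    prov.update(
        {
            "manual_edit": bool(add.any() or remove.any()),
            "voxels_added": int((add & ~mask.data).sum()),
            "voxels_removed": int((remove & mask.data).sum()),
        }
    )
    return VeinMask(data=out, spacing=mask.spacing, provenance=prov)


def qc_overlay(mip: MipStack, mask: VeinMask, color=(1.0, 0.0, 0.0)) -> np.ndarray:
    """RGB stack with the mask boundary drawn over normalised mIP slices.

    Pure rendering for visual review; shape (nx, ny, nz, 3) in [0, 1].
    """
    if mip.data.shape != mask.data.shape:
        raise ValueError("mIP and vein mask grids differ")
    lo, hi = float(mip.data.min()), float(mip.data.max())
    gray = (mip.data - lo) / (hi - lo) if hi > lo else np.zeros_like(mip.data)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    boundary = np.zeros_like(mask.data)
    for z in range(mask.data.shape[2]):
        sl = mask.data[:, :, z]
        if sl.any():
            boundary[:, :, z] = sl & ~ndimage.binary_erosion(sl)
    rgb[boundary] = color
    return rgb
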