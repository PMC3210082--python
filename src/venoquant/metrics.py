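"""Venous-vasculature-visibility (VVV) indices.

ATVV: apparent total venous volume — vein-voxel count times voxel volume,
in ml; "apparent" because mIP projection inflates small-vein visibility, so
the measure is relative rather than absolute. VIF: ATVV normalised by the
intracranial volume to correct for head size. DFV: per-voxel Euclidean
distance (mm, anisotropic spacing honoured) to the nearest vein voxel; its
brain-wide mean is an inverse proxy for local vein density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .diameter_classify import DiameterClassMap, N_CLASSES
from .vein_extract import VeinMask

__all__ = ["VvvReport", "atvv", "vif", "dfv_map", "mean_dfv", "compute_vvv_report"]


@dataclass
class VvvReport:
    """Per-subject VVV scalars."""

    atvv_total_ml: float
    atvv_by_class_ml: dict[int, float]
    vif: float
    mean_dfv_mm: float
    icv_ml: float
    condition: str = "pre"  # contrast condition: pre | post

    def __post_init__(self) -> None:
        class_sum = sum(self.atvv_by_class_ml.values())
        if abs(class_sum - self.atvv_total_ml) > 1e-6:
            raise ValueError(
                f"class ATVVs sum to {class_sum}, total is {self.atvv_total_ml}"
            )
        if min(self.atvv_total_ml, self.vif, self.mean_dfv_mm, self.icv_ml) < 0:
            raise ValueError("VVV values must be non-negative")

    def as_dict(self) -> dict:
        d = {
            "condition": self.condition,
            "atvv_total_ml": self.atvv_total_ml,
            "vif": self.vif,
            "mean_dfv_mm": self.mean_dfv_mm,
            "icv_ml": self.icv_ml,
        }
        for k in range(1, N_CLASSES + 1):
            d[f"atvv_class{k}_ml"] = self.atvv_by_class_ml.get(k, 0.0)
        return d


def atvv(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Voxel count x voxel volume (mm**3) / 1000 -> ml."""
    if min(spacing) <= 0:
        raise ValueError("spacing must be positive")
    voxel_mm3 = float(np.prod(spacing))
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def vif(atvv_ml: float, icv_ml: float) -> float:
    """Venous intracranial fraction: ATVV / ICV."""
    if icv_ml <= 0:
        raise ValueError("intracranial volume must be > 0")
    return atvv_ml / icv_ml


def dfv_map(
    veins: VeinMask, brain: np.ndarray, spacing: tuple[float, float, float] | None = None
) -> np.ndarray:
    """Distance-from-vein map over the brain, mm.

    Euclidean distance transform of the vein-mask complement with anisotropic
    voxel sampling; NaN outside the brain mask, 0 on vein voxels.
    """
    brain = np.asarray(brain, dtype=bool)
    if brain.shape != veins.data.shape:
        raise ValueError("vein and brain grids differ")
    if not veins.data.any():
        raise ValueError("no veins segmented")
    sp = spacing if spacing is not None else veins.spacing
    dist = ndimage.distance_transform_edt(~veins.data, sampling=sp)
    out = np.where(brain, dist, np.nan)
    return out


def mean_dfv(dfv: np.ndarray, brain: np.ndarray, include_veins: bool = True) -> float:
    """Arithmetic mean of the DFV map over brain voxels.

    ``include_veins=False`` averages over non-vein brain voxels only
    (vein voxels are the zeros of the map).
    """
    brain = np.asarray(brain, dtype=bool)
    if not brain.any():
        raise ValueError("brain mask is empty")
    vals = np.asarray(dfv, dtype=float)[brain]
    vals = vals[np.isfinite(vals)]
    if not include_veins:
        vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no voxels to average")
    return float(vals.mean())


def compute_vvv_report(
    class_map: DiameterClassMap,
    veins: VeinMask,
    brain: np.ndarray,
    icv_ml: float,
    condition: str = "pre",
    include_veins_in_dfv: bool = True,
) -> VvvReport:
    """Assemble the per-subject VVV report.

    ATVV (total and per class) is computed on the upsampled class-map grid
    with the matching voxel volume; DFV on the native vein-mask grid.
    """
    by_class = {
        k: atvv(class_map.class_mask(k), class_map.spacing) for k in range(1, N_CLASSES + 1)
    }
    total = atvv(class_map.labels > 0, class_map.spacing)
    dfv = dfv_map(veins, brain)
    return VvvReport(
        atvv_total_ml=total,
        atvv_by_class_ml=by_class,
        vif=vif(total, icv_ml),
        mean_dfv_mm=mean_dfv(dfv, brain, include_veins=include_veins_in_dfv),
        icv_ml=icv_ml,
        condition=condition,
    )
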