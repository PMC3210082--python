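"""Pipeline driver: recon -> vesselness -> extract -> classify -> metrics.

Runs the enabled stages in order on one subject's inputs, carrying
provenance (config hash, per-stage parameters) through to the report.
Identical config + inputs + seed give bit-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time

import numpy as np

from . import metrics, swi_recon, vein_extract, vesselness
from .config import PipelineConfig
from .diameter_classify import classify_diameters
from .swi_recon import ComplexChannelData, SwiVolume

log = logging.getLogger("venoquant")

__all__ = ["run_pipeline", "report_hash"]


def _require(inputs: dict, key: str, stage: str):
    if key not in inputs or inputs[key] is None:
        raise ValueError(f"stage '{stage}' requires input '{key}'")
    return inputs[key]


def run_pipeline(
    config: PipelineConfig,
    inputs: dict,
    subject: str = "subject",
    classify: bool = True,
) -> dict:
    """Execute the VVV pipeline for one subject.

    ``inputs`` may contain:

    * ``kspace`` (ComplexChannelData) — full reconstruction, or
    * ``magnitude`` + ``complex`` arrays with ``spacing`` — skip zero-fill, or
    * ``swi`` (SwiVolume) — skip reconstruction entirely;
    * ``brain`` (bool array on the mIP grid) — required for extraction;
    * ``icv_ml`` — defaults to the brain-mask volume;
    * optional ``edits_add`` / ``edits_remove`` masks.

    Returns a dict with the per-subject report, provenance and the
    intermediate artifacts (mip, vesselness, vein mask, class map).
    """
    t0 = time.time()
    artifacts: dict = {}

    if "swi" in inputs and inputs["swi"] is not None:
        swi: SwiVolume = inputs["swi"]
    else:
        if "kspace" in inputs and inputs["kspace"] is not None:
            ks: ComplexChannelData = inputs["kspace"]
            target = config.target_matrix or tuple(ks.matrix)
            channel_imgs, spacing = swi_recon.zero_fill_reconstruct(ks, target)
            magnitude, _ = swi_recon.recombine_channels(channel_imgs)
            combined = np.sum(
                [channel_imgs[c] for c in range(channel_imgs.shape[0])], axis=0
            )
        else:
            magnitude = np.asarray(_require(inputs, "magnitude", "recon"), dtype=float)
            combined = np.asarray(_require(inputs, "complex", "recon"))
            spacing = tuple(_require(inputs, "spacing", "recon"))
        log.info("recon: grid %s spacing %s", magnitude.shape, spacing)
        corrected = swi_recon.correct_bias(
            magnitude, scale_mm=config.bias_scale_mm, spacing=spacing,
            external=inputs.get("bias_corrected"),
        )
        window = tuple(min(w, s) for w, s in zip(config.hanning_window, magnitude.shape[:2]))
        phase = swi_recon.highpass_phase(combined, window=window)
        mask = swi_recon.phase_mask(phase, polarity=config.mask_polarity)
        swi = swi_recon.apply_mask(
            corrected, mask, n=config.mask_power, spacing=spacing,
            provenance={"window": list(window), "polarity": config.mask_polarity},
        )
    artifacts["swi"] = swi

    mip = swi_recon.min_intensity_projection(
        swi, thickness=min(config.mip_thickness, swi.data.shape[2]), step=config.mip_step
    )
    artifacts["mip"] = mip

    params = vesselness.VesselnessParams(
        sigma_min_mm=config.sigma_min_mm, sigma_max_mm=config.sigma_max_mm,
        n_scales=config.n_scales, alpha1=config.alpha1, alpha2=config.alpha2,
        weighted=config.weighted_vesselness, threshold=config.vesselness_threshold,
    )
    vess, scales = vesselness.multiscale_vesselness(mip.data, params, spacing=mip.spacing)
    if params.weighted and vess.max() > 0:
        vess = vess / vess.max()  # relative threshold on the weighted response
    artifacts["vesselness"] = vess
    artifacts["argmax_scale_mm"] = scales

    brain = np.asarray(_require(inputs, "brain", "extract"), dtype=bool)
    if brain.shape != mip.data.shape:
        if brain.shape[:2] == mip.data.shape[:2] and brain.shape[2] >= mip.data.shape[2]:
            brain = brain[:, :, : mip.data.shape[2]]  # mIP shortens the stack
        else:
            raise ValueError("stage 'extract': brain mask grid mismatch")
    veins = vein_extract.threshold_vesselness(
        vess, params.threshold, brain, spacing=mip.spacing
    )
    veins = vein_extract.size_filter(veins, config.min_component_voxels)
    if inputs.get("edits_add") is not None or inputs.get("edits_remove") is not None:
        add = inputs.get("edits_add")
        rem = inputs.get("edits_remove")
        zeros = np.zeros_like(veins.data)
        veins = vein_extract.apply_manual_edits(
            veins, add if add is not None else zeros, rem if rem is not None else zeros
        )
    artifacts["veins"] = veins

    icv_ml = float(
        inputs.get("icv_ml")
        or brain.sum() * np.prod(mip.spacing) / 1000.0
    )
    report: dict = {"subject": subject}
    if classify:
        class_map = classify_diameters(veins, min_voxels=config.min_component_voxels)
        artifacts["class_map"] = class_map
        vvv = metrics.compute_vvv_report(
            class_map, veins, brain, icv_ml,
            condition=inputs.get("condition", "pre"),
            include_veins_in_dfv=config.dfv_include_veins,
        )
        report.update(vvv.as_dict())
    else:
        total = metrics.atvv(veins.data, veins.spacing)
        dfv = metrics.dfv_map(veins, brain)
        report.update(
            {
                "condition": inputs.get("condition", "pre"),
                "atvv_total_ml": total,
                "vif": metrics.vif(total, icv_ml),
                "mean_dfv_mm": metrics.mean_dfv(dfv, brain, config.dfv_include_veins),
                "icv_ml": icv_ml,
            }
        )

    report["config_hash"] = config.config_hash()
    report["seed"] = config.seed
    log.info("pipeline for %s done in %.1f s", subject, time.time() - t0)
    return {"report": report, "artifacts": artifacts, "config": config.as_dict()}


def report_hash(report: dict) -> str:
    """Stable hash of a per-subject report for determinism checks."""
    blob = json.dumps(report, sort_keys=True, default=repr)
    return hashlib.sha256(blob.encode()).hexdigest()
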