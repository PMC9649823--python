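"""End-to-end pipeline: preprocess -> predict -> post-process -> volume -> reports.

Each stage records its parameters into a JSON provenance sidecar so a run is
reproducible from its report bundle alone; with a fixed seed and config the
bundle is byte-identical across runs. Stage failures halt with the stage
name attached.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import agreement, postvolume, preprocess
from .errors import LocalizationError, RenovolError, StageError
from .imaging import ClassScheme, CTVolume, LabelMap, load_labelmap, load_volume, save_labelmap
from .nn.infer import predict_probabilities, probabilities_to_labels
from .nn.train import Checkpoint, map_labels_to_network_classes
from .reference import DogRecord, packaged_models, predict_reference_volume

logger = logging.getLogger("renovol")

__all__ = ["PipelineConfig", "run_end_to_end", "preprocess_volume"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run (paths may be None for in-memory use)."""

    input_path: str | None = None
    labels_path: str | None = None
    checkpoint_path: str | None = None
    output_dir: str | None = None
    phase: str = "post_contrast"
    target_spacing: tuple[float, float, float] = preprocess.TARGET_SPACING
    background_hu: float = -900.0
    lung_params: preprocess.LungDetectionParams = field(default_factory=preprocess.LungDetectionParams)
    expected_components: int = 2
    max_major_components: int = 4
    connectivity: int = 26
    min_separation_mm: float = 20.0
    reference_model: str | None = None
    dog: dict | None = None
    seed: int = 0


def preprocess_volume(vol: CTVolume, cfg: PipelineConfig, labels: LabelMap | None = None):
    """Crop, localize, resample and normalize; labels follow the same grid ops.

    Returns ``(normalized volume, resampled labels or None, provenance dict)``.
    """
    _, body_box = preprocess.crop_nonzero(vol, cfg.background_hu)
    try:
        kidney_box = preprocess.localize_kidney_region(vol, cfg.lung_params)
        localized = True
    except LocalizationError:
        logger.warning("lung localization failed; falling back to the body crop")
        kidney_box, localized = body_box, False
    cropped = preprocess.crop_to_box(vol, kidney_box)
    resampled = preprocess.resample(cropped, cfg.target_spacing)
    normalized = preprocess.normalize_intensity(resampled)
    out_labels = None
    if labels is not None:
        out_labels = preprocess.resample(preprocess.crop_to_box(labels, kidney_box), cfg.target_spacing)
    prov = {
        "body_box": body_box.to_dict(),
        "kidney_box": kidney_box.to_dict(),
        "localized": localized,
        "target_spacing": list(cfg.target_spacing),
        "background_hu": cfg.background_hu,
        "lung_params": asdict(cfg.lung_params),
    }
    return normalized, out_labels, prov


def run_end_to_end(cfg: PipelineConfig, vol: CTVolume | None = None,
                   labels: LabelMap | None = None,
                   checkpoint: Checkpoint | None = None) -> dict:
    """Execute the full pipeline and return (and optionally write) the report bundle."""
    t0 = time.time()
    provenance = {"seed": cfg.seed, "stages": {}}

    scheme = ClassScheme.pre_contrast() if cfg.phase == "pre_contrast" else ClassScheme.post_contrast()
    try:
        if vol is None:
            if cfg.input_path is None:
                raise StageError("input", "no input volume provided")
            vol = load_volume(cfg.input_path)
        if labels is None and cfg.labels_path:
            labels = load_labelmap(cfg.labels_path, scheme)
    except RenovolError:
        raise
    except Exception as exc:
        raise StageError("input", str(exc)) from exc

    try:
        normalized, gt_labels, prov = preprocess_volume(vol, cfg, labels)
        provenance["stages"]["preprocess"] = prov
    except RenovolError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("preprocess", str(exc)) from exc

    try:
        if checkpoint is None:
            if not cfg.checkpoint_path:
                raise StageError("segnet", "no checkpoint provided and training is disabled")
            checkpoint = Checkpoint.load(cfg.checkpoint_path)
        prob = predict_probabilities(checkpoint, normalized)
        pred = probabilities_to_labels(prob)
        provenance["stages"]["predict"] = {
            "checkpoint_fingerprint": checkpoint.fingerprint,
            "checkpoint_epoch": checkpoint.epoch,
            "checkpoint_val_dsc": checkpoint.val_dsc,
        }
    except RenovolError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("segnet", str(exc)) from exc

    try:
        cleaned = postvolume.postprocess_labels(
            pred, cfg.expected_components, cfg.max_major_components,
            cfg.connectivity, cfg.min_separation_mm,
        )
        volumes = postvolume.voxel_count_volume(cleaned)
        provenance["stages"]["postvolume"] = {
            "expected_components": cfg.expected_components,
            "max_major": cfg.max_major_components,
            "connectivity": cfg.connectivity,
            "min_separation_mm": cfg.min_separation_mm,
        }
    except RenovolError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("postvolume", str(exc)) from exc

    report = {
        "volumes": volumes.to_dict(),
        "provenance": provenance,
    }

    if gt_labels is not None:
        gt_net = map_labels_to_network_classes(gt_labels.labels, gt_labels.scheme)
        pred_par = cleaned.parenchyma_mask()
        gt_par = np.isin(gt_net, (1, 2))
        gt_volumes = postvolume.voxel_count_volume(gt_labels)
        report["agreement"] = {
            "parenchyma_dsc": agreement.dsc(pred_par, gt_par),
            "gt_parenchyma_cm3": gt_volumes.volumes_cm3["parenchyma"],
            "auto_parenchyma_cm3": volumes.volumes_cm3["parenchyma"],
        }

    if cfg.reference_model:
        models = packaged_models()
        if cfg.reference_model not in models:
            raise StageError("reference", f"unknown model {cfg.reference_model!r}")
        dog = DogRecord(**(cfg.dog or {"id": "case"}),
                        measured_volume=volumes.volumes_cm3["parenchyma"])
        expected, ratio = predict_reference_volume(dog, models[cfg.reference_model])
        report["reference"] = {
            "model": cfg.reference_model,
            "expected_cm3": expected,
            "measured_over_expected": ratio,
        }

    report["runtime_s"] = round(time.time() - t0, 3)

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_labelmap(cleaned, out / "prediction.nii.gz")
        # runtime is wall-clock and would break byte-identical reruns; keep it
        # out of the persisted bundle
        persisted = {k: v for k, v in report.items() if k != "runtime_s"}
        (out / "report.json").write_text(json.dumps(persisted, indent=2, sort_keys=True))
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return report
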