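"""Two-stage inference: bone-region segmentation, then implant-ROI
segmentation conditioned on the first stage's output.

Stage 1 runs the slice/resize/predict/restore/stack loop on the whole
(normalised) volume and binarises at the configured threshold. Stage 2
builds its input from the stage-1 mask — by default the voxel-wise
product of the normalised intensity and the mask (``masked_intensity``),
which enforces the cascade while preserving the bone texture; the
``mask_only`` mode feeds the binary mask itself — and repeats the same
slice-wise pass. The full masked volume is fed to stage 2 (no cropping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .slicer import (SliceRecord, SliceStack, fuse_axis_predictions,
                     resize_slice, restore_slice, slice_volume, stack_slices)
from .unet2d import SliceUNet
from .volume_io import BinaryMask3D, CBCTVolume


@dataclass
class CascadeConfig:
    threshold: float = 0.5
    fusion_mode: str = "single_axis"  # single_axis | mean | majority
    stage2_input: str = "masked_intensity"  # masked_intensity | mask_only
    prediction_axis: int = 2
    fusion_axes: tuple[int, ...] = (0, 1, 2)
    keep_largest_component: bool = False

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.stage2_input not in ("masked_intensity", "mask_only"):
            raise ValueError(f"unknown stage2_input {self.stage2_input!r}")


@dataclass
class CaseResult:
    bone_prob: np.ndarray
    bone_mask: BinaryMask3D
    implant_prob: np.ndarray
    implant_mask: BinaryMask3D
    metrics: dict | None = None
    provenance: dict = field(default_factory=dict)


def _check_fitted(model: SliceUNet, stage: str):
    if not hasattr(model, "net_"):
        raise RuntimeError(f"{stage} model is not trained")


def predict_volume(model: SliceUNet, data: np.ndarray, spacing, cfg:
                   CascadeConfig) -> np.ndarray:
    """slice -> resize -> predict -> restore -> stack for one 3D array."""
    target = tuple(model.input_shape)
    # container used purely for slicing; units tag irrelevant here
    vol = CBCTVolume(data.astype(np.float32), spacing, units="HU")
    axes = (cfg.fusion_axes if cfg.fusion_mode != "single_axis"
            else (cfg.prediction_axis,))
    per_axis = []
    for axis in axes:
        stack = slice_volume(vol, axes=(axis,))
        X = np.stack([resize_slice(r, target).image for r in stack.records])
        probs = model.predict_proba(X)
        restored = [restore_slice(SliceRecord(
            image=probs[i], axis=r.axis, index=r.index,
            native_shape=r.native_shape, case_id=r.case_id))
            for i, r in enumerate(stack.records)]
        per_axis.append(stack_slices(
            SliceStack(restored, stack.source_shape, stack.spacing_mm)))
    return fuse_axis_predictions(per_axis, mode=cfg.fusion_mode,
                                 designated=0, threshold=cfg.threshold)


def _binarize(prob: np.ndarray, spacing, cfg: CascadeConfig) -> BinaryMask3D:
    mask = prob >= cfg.threshold
    if cfg.keep_largest_component and mask.any():
        from scipy import ndimage
        lab, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return BinaryMask3D(mask, spacing)


def segment_bone(model1: SliceUNet, vol: CBCTVolume, cfg: CascadeConfig
                 ) -> tuple[np.ndarray, BinaryMask3D]:
    """Stage 1: missing-tooth bone region from the whole volume."""
    _check_fitted(model1, "stage-1")
    if vol.units != "normalized":
        raise ValueError("segment_bone expects a windowed, normalised volume")
    prob = predict_volume(model1, vol.data, vol.spacing_mm, cfg)
    return prob, _binarize(prob, vol.spacing_mm, cfg)


def build_stage2_input(vol: CBCTVolume, bone_mask: BinaryMask3D,
                       cfg: CascadeConfig) -> np.ndarray:
    if bone_mask.shape != vol.shape:
        raise ValueError(
            f"bone mask shape {bone_mask.shape} != volume shape {vol.shape}")
    if cfg.stage2_input == "mask_only":
        return bone_mask.data.astype(np.float32)
    return (vol.data * bone_mask.data).astype(np.float32)


def segment_implant(model2: SliceUNet, vol: CBCTVolume,
                    bone_mask: BinaryMask3D, cfg: CascadeConfig
                    ) -> tuple[np.ndarray, BinaryMask3D]:
    """Stage 2: implant ROI from the stage-1-conditioned input."""
    _check_fitted(model2, "stage-2")
    stage2 = build_stage2_input(vol, bone_mask, cfg)
    prob = predict_volume(model2, stage2, vol.spacing_mm, cfg)
    return prob, _binarize(prob, vol.spacing_mm, cfg)


def run_pipeline(vol: CBCTVolume, model1: SliceUNet, model2: SliceUNet,
                 cfg: CascadeConfig | None = None, truth=None) -> CaseResult:
    """Both cascade stages; metrics computed when ground truth is given.

    ``truth`` is a phantom case (or any object with ``bone_region_mask``
    and ``implant_mask`` attributes) on the same grid.
    """
    from .seg_metrics import full_report
    cfg = cfg or CascadeConfig()
    bone_prob, bone_mask = segment_bone(model1, vol, cfg)
    implant_prob, implant_mask = segment_implant(model2, vol, bone_mask, cfg)
    metrics = None
    if truth is not None:
        metrics = {
            "bone": full_report(truth.bone_region_mask, bone_mask,
                                spacing=vol.spacing_mm),
            "implant": full_report(truth.implant_mask, implant_mask,
                                   spacing=vol.spacing_mm),
        }
    prov = dict(config=vars(cfg).copy(),
                model1_seed=model1.seed, model2_seed=model2.seed)
    return CaseResult(bone_prob, bone_mask, implant_prob, implant_mask,
                      metrics, prov)


class CascadeSegmenter:
    """Volume-level meta-estimator wrapping the two slice U-Nets.

    ``fit`` trains both stages on a list of phantom-style cases (objects
    with ``volume``, ``bone_region_mask``, ``implant_mask``, ``case_id``);
    ``predict`` runs the cascade on one normalised volume. Training slices
    are taken along ``config.prediction_axis`` with an optional
    subsampling step (every ``slice_step``-th slice), and the train/val
    split is case-level.
    """

    def __init__(self, stage1: SliceUNet | None = None,
                 stage2: SliceUNet | None = None,
                 config: CascadeConfig | None = None,
                 slice_step: int = 1, validation_fraction: float = 0.2,
                 seed: int = 0):
        self.stage1 = stage1 or SliceUNet(seed=seed)
        self.stage2 = stage2 or SliceUNet(seed=seed + 1)
        self.config = config or CascadeConfig()
        self.slice_step = slice_step
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- helpers -------------------------------------------------------
    def _slice_xy(self, data: np.ndarray, target, is_mask: bool,
                  spacing) -> np.ndarray:
        container = (BinaryMask3D(data, spacing) if is_mask
                     else CBCTVolume(data, spacing, units="HU"))
        stack = slice_volume(container, axes=(self.config.prediction_axis,))
        recs = stack.records[::self.slice_step]
        return np.stack([resize_slice(r, target).image.astype(np.float32)
                         for r in recs])

    def _training_arrays(self, cases, stage: str):
        from .unet2d import split_dataset
        from .volume_io import normalize_intensity, window_hu
        target = tuple(self.stage1.input_shape)
        train_cases, val_cases = split_dataset(
            cases, fraction=self.validation_fraction, unit="volume",
            seed=self.seed)
        out = []
        for subset in (train_cases, val_cases):
            xs, ys = [], []
            for case in subset:
                vol = normalize_intensity(window_hu(case.volume))
                if stage == "bone":
                    xdata = vol.data
                    ymask = case.bone_region_mask
                else:
                    xdata = build_stage2_input(vol, case.bone_region_mask,
                                               self.config)
                    ymask = case.implant_mask
                xs.append(self._slice_xy(xdata, target, False,
                                         vol.spacing_mm))
                ys.append(self._slice_xy(ymask.data, target, True,
                                         vol.spacing_mm))
            out.append((np.concatenate(xs), np.concatenate(ys)))
        return out

    # -- estimator surface ---------------------------------------------
    def fit(self, cases) -> "CascadeSegmenter":
        (xt, yt), (xv, yv) = self._training_arrays(cases, "bone")
        self.stage1.fit(xt, yt, X_val=xv, y_val=yv)
        (xt, yt), (xv, yv) = self._training_arrays(cases, "implant")
        self.stage2.fit(xt, yt, X_val=xv, y_val=yv)
        return self

    def predict(self, vol: CBCTVolume, truth=None) -> CaseResult:
        return run_pipeline(vol, self.stage1, self.stage2, self.config,
                            truth=truth)
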