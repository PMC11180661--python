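"""Synthetic-phantom benchmark protocol for the two cascade stages.

This module defines the package's reference evaluation: a seeded phantom
cohort of 30 cases (24 train / 6 held-out test) on the standardized
79 x 112 x 135 grid with 40 HU noise, slice-wise training along the
stacking axis, and the full metric report on the held-out cases.

Problem sizes are chosen for a single-CPU desk run: training slices are
subsampled (every 5th slice along the prediction axis — adjacent 0.3 mm
slices are nearly duplicates) and each stage trains for 32 epochs with a
case-level 80/20 train/validation split inside the training cohort and a
stepped learning-rate decay late in training.

Stage 1 ("bone") trains and evaluates the missing-tooth bone-region
model on the whole normalised volume. Stage 2 ("implant") trains and
evaluates the implant-ROI model with its input conditioned on the
ground-truth bone-region mask, isolating stage-2 quality from stage-1
errors; the cascaded variant (stage-2 conditioned on the stage-1
prediction) is available via :class:`~dentseg.cascade.CascadeSegmenter`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import CascadeConfig, CascadeSegmenter, segment_bone, \
    segment_implant
from .phantom import PhantomSpec, generate_cohort
from .seg_metrics import MetricsReport, full_report
from .unet2d import SliceUNet
from .volume_io import normalize_intensity, window_hu


@dataclass
class BenchmarkProtocol:
    """Study conditions + runtime scale of the reference benchmark."""

    n_train: int = 24
    n_test: int = 6
    grid_shape: tuple[int, int, int] = (79, 112, 135)
    voxel_spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    noise_sd_hu: float = 40.0
    epochs: int = 32
    slice_step: int = 5
    batch_size: int = 32
    prediction_axis: int = 2
    threshold: float = 0.5
    validation_fraction: float = 0.2


@dataclass
class StageResult:
    stage: str
    reports: list[MetricsReport]
    mean_dice: float
    mean_volume_error_rate: float
    n_test: int
    history: list = field(default_factory=list)

    @classmethod
    def from_reports(cls, stage, reports, history=None):
        return cls(stage=stage, reports=reports,
                   mean_dice=float(np.mean([r.dice for r in reports])),
                   mean_volume_error_rate=float(
                       np.mean([r.volume_error_rate for r in reports])),
                   n_test=len(reports), history=history or [])


def benchmark_cohort(protocol: BenchmarkProtocol, seed: int):
    spec = PhantomSpec(grid_shape=protocol.grid_shape,
                       voxel_spacing_mm=protocol.voxel_spacing_mm,
                       noise_sd_hu=protocol.noise_sd_hu)
    cases = generate_cohort(protocol.n_train + protocol.n_test, spec,
                            seed=seed)
    return cases[:protocol.n_train], cases[protocol.n_train:]


def run_stage_benchmark(stage: str, seed: int = 0,
                        protocol: BenchmarkProtocol | None = None,
                        cohort=None, verbose: bool = False) -> StageResult:
    """Train one stage on a seeded cohort and evaluate the held-out cases.

    ``stage`` is ``"bone"`` (model 1: bone region from the whole volume)
    or ``"implant"`` (model 2: implant ROI from the intensity volume
    masked by the ground-truth bone region).
    """
    if stage not in ("bone", "implant"):
        raise ValueError(f"unknown stage {stage!r}")
    protocol = protocol or BenchmarkProtocol()
    train_cases, test_cases = (cohort if cohort is not None
                               else benchmark_cohort(protocol, seed))

    cfg = CascadeConfig(threshold=protocol.threshold,
                        prediction_axis=protocol.prediction_axis)
    model = SliceUNet(epochs=protocol.epochs,
                      batch_size=protocol.batch_size,
                      seed=seed, verbose=verbose)
    seg = CascadeSegmenter(stage1=model, stage2=model, config=cfg,
                           slice_step=protocol.slice_step,
                           validation_fraction=protocol.validation_fraction,
                           seed=seed)
    (xt, yt), (xv, yv) = seg._training_arrays(train_cases, stage)
    model.fit(xt, yt, X_val=xv, y_val=yv)

    reports = []
    for case in test_cases:
        vol = normalize_intensity(window_hu(case.volume))
        if stage == "bone":
            _, mask = segment_bone(model, vol, cfg)
            truth = case.bone_region_mask
        else:
            _, mask = segment_implant(model, vol, case.bone_region_mask, cfg)
            truth = case.implant_mask
        reports.append(full_report(truth, mask, spacing=vol.spacing_mm))
    return StageResult.from_reports(stage, reports, model.history_)


def tri_axial_slice_count(n_volumes: int = 150,
                          grid_shape=(79, 112, 135)) -> int:
    """Slices produced by cutting ``n_volumes`` along all three axes."""
    from .slicer import slice_volume
    from .volume_io import CBCTVolume
    probe = CBCTVolume(np.zeros(grid_shape, dtype=np.float32))
    per_volume = len(slice_volume(probe, axes=(0, 1, 2)))
    return n_volumes * per_volume
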