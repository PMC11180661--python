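"""Cascade orchestration: thresholding, conditioning, determinism."""

import numpy as np
import pytest

from dentseg.cascade import (CascadeConfig, CascadeSegmenter, CaseResult,
                             build_stage2_input, run_pipeline, segment_bone)
from dentseg.unet2d import SliceUNet
from dentseg.volume_io import BinaryMask3D, normalize_intensity, window_hu


@pytest.fixture(scope="module")
def tiny_models(small_case):
    """Two minimally trained models — enough to exercise the plumbing."""
    from dentseg.phantom import generate_cohort
    cases = generate_cohort(3, small_case.spec, seed=21)
    seg = CascadeSegmenter(
        stage1=SliceUNet(epochs=1, seed=0),
        stage2=SliceUNet(epochs=1, seed=1),
        config=CascadeConfig(), slice_step=8,
        validation_fraction=0.34, seed=0)
    seg.fit(cases)
    return seg


def _norm(case):
    return normalize_intensity(window_hu(case.volume))


def test_config_validation():
    with pytest.raises(ValueError):
        CascadeConfig(threshold=0.0)
    with pytest.raises(ValueError):
        CascadeConfig(stage2_input="bogus")


def test_untrained_model_rejected(small_case):
    with pytest.raises(RuntimeError, match="not trained"):
        segment_bone(SliceUNet(), _norm(small_case), CascadeConfig())


def test_raw_volume_rejected(tiny_models, small_case):
    with pytest.raises(ValueError, match="normalis"):
        segment_bone(tiny_models.stage1, small_case.volume, CascadeConfig())


def test_probabilities_bounded_and_threshold_monotone(tiny_models,
                                                      small_case):
    vol = _norm(small_case)
    prob, _ = segment_bone(tiny_models.stage1, vol, CascadeConfig())
    assert prob.shape == vol.shape
    assert prob.min() >= 0 and prob.max() <= 1
    counts = [(prob >= t).sum() for t in (0.3, 0.5, 0.7)]
    assert counts[0] >= counts[1] >= counts[2]
    # stored mask is exactly prob >= threshold
    cfg = CascadeConfig(threshold=0.5)
    prob2, mask = segment_bone(tiny_models.stage1, vol, cfg)
    assert np.array_equal(mask.data, prob2 >= 0.5)


def test_stage2_input_modes(small_case):
    vol = _norm(small_case)
    empty = BinaryMask3D(np.zeros(vol.shape, dtype=bool), vol.spacing_mm)
    assert not build_stage2_input(vol, empty,
                                  CascadeConfig()).any()
    full = small_case.bone_region_mask
    masked = build_stage2_input(vol, full, CascadeConfig())
    assert np.array_equal(masked[full.data], vol.data[full.data])
    assert not masked[~full.data].any()
    mask_only = build_stage2_input(
        vol, full, CascadeConfig(stage2_input="mask_only"))
    assert set(np.unique(mask_only)) <= {0.0, 1.0}
    with pytest.raises(ValueError, match="shape"):
        bad = BinaryMask3D(np.zeros((3, 3, 3), dtype=bool))
        build_stage2_input(vol, bad, CascadeConfig())


def test_run_pipeline_shapes_metrics_and_determinism(tiny_models,
                                                     small_case):
    vol = _norm(small_case)
    res = run_pipeline(vol, tiny_models.stage1, tiny_models.stage2,
                       tiny_models.config, truth=small_case)
    assert isinstance(res, CaseResult)
    for grid in (res.bone_prob, res.implant_prob,
                 res.bone_mask.data, res.implant_mask.data):
        assert grid.shape == vol.shape
    assert set(res.metrics) == {"bone", "implant"}
    res_nt = run_pipeline(vol, tiny_models.stage1, tiny_models.stage2,
                          tiny_models.config)
    assert res_nt.metrics is None
    res2 = run_pipeline(vol, tiny_models.stage1, tiny_models.stage2,
                        tiny_models.config)
    assert np.array_equal(res.bone_prob, res2.bone_prob)
    assert np.array_equal(res.implant_mask.data, res2.implant_mask.data)


def test_perfect_prediction_limit(small_case):
    """Injecting ground truth as prediction yields Dice 1 on both stages."""
    from dentseg.seg_metrics import full_report
    rb = full_report(small_case.bone_region_mask,
                     small_case.bone_region_mask)
    ri = full_report(small_case.implant_mask, small_case.implant_mask)
    assert rb.dice == 1.0 and ri.dice == 1.0
    assert rb.volume_error_rate == 0.0


def test_largest_component_filter(tiny_models, small_case):
    vol = _norm(small_case)
    cfg = CascadeConfig(keep_largest_component=True)
    _, mask = segment_bone(tiny_models.stage1, vol, cfg)
    if mask.data.any():
        from scipy import ndimage
        _, n = ndimage.label(mask.data)
        assert n == 1
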