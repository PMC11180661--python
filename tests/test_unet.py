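"""Network architecture contract, gradients, training behaviour."""

import numpy as np
import pytest

from dentseg.nn import UNet2D
from dentseg.nn.losses import bce_dice_loss_and_grad, sigmoid, soft_dice
from dentseg.unet2d import (AugmentConfig, Augmenter, SliceUNet,
                            TrainingError, UNetConfig, build_unet,
                            split_dataset)


def test_feature_doubling_schedule():
    net = build_unet(UNetConfig())
    assert net.feature_widths == [32, 64, 128, 256]
    small = UNet2D(in_shape=(8, 8), levels=3, initial_features=4)
    assert small.feature_widths == [4, 8, 16]


def test_shape_contract_and_sigmoid_head(rng):
    net = build_unet(UNetConfig())
    x = np.zeros((2, 24, 24, 1), dtype=np.float32)
    z = net.forward(x)
    assert z.shape == (2, 24, 24, 1)
    p = sigmoid(z)
    assert ((p > 0) & (p < 1)).all()


def test_indivisible_input_rejected():
    with pytest.raises(ValueError, match="divisible"):
        UNet2D(in_shape=(24, 24), levels=5)
    with pytest.raises(ValueError, match="divisible"):
        UNet2D(in_shape=(23, 24), levels=4)


def test_seeded_init_reproducible():
    a = UNet2D(in_shape=(8, 8), levels=2, initial_features=4, seed=7)
    b = UNet2D(in_shape=(8, 8), levels=2, initial_features=4, seed=7)
    c = UNet2D(in_shape=(8, 8), levels=2, initial_features=4, seed=8)
    for (wa, _), (wb, _) in zip(a.params, b.params):
        assert np.array_equal(wa, wb)
    assert any(not np.array_equal(wa, wc)
               for (wa, _), (wc, _) in zip(a.params, c.params))


def test_analytic_gradients_match_finite_differences(rng):
    net = UNet2D(in_shape=(8, 8), levels=3, blocks_per_level=2,
                 initial_features=3, seed=1, dtype=np.float64)
    x = rng.normal(size=(2, 8, 8, 1))
    y = (rng.random((2, 8, 8, 1)) > 0.7).astype(float)
    z = net.forward(x, train=True)
    _, g = bce_dice_loss_and_grad(z, y)
    net.backward(g)
    analytic = [dg.copy() for _, dg in net.params]
    w0 = net.get_weights()

    def loss_at(ws):
        net.set_weights(ws)
        return bce_dice_loss_and_grad(net.forward(x, train=True), y)[0]

    eps = 1e-6
    pick = np.random.default_rng(2)
    for pi in pick.choice(len(w0), size=6, replace=False):
        flat_idx = pick.integers(w0[pi].size)
        ws = [w.copy() for w in w0]
        ws[pi].ravel()[flat_idx] += eps
        lp = loss_at(ws)
        ws[pi].ravel()[flat_idx] -= 2 * eps
        lm = loss_at(ws)
        num = (lp - lm) / (2 * eps)
        ana = analytic[pi].ravel()[flat_idx]
        assert num == pytest.approx(ana, rel=1e-4, abs=1e-8)


def test_loss_minimum_at_perfect_prediction(rng):
    y = (rng.random((1, 8, 8, 1)) > 0.5).astype(np.float32)
    z = np.where(y > 0, 40.0, -40.0).astype(np.float32)
    loss, _ = bce_dice_loss_and_grad(z, y, "bce_plus_dice")
    assert loss < 1e-3


def test_batch_equals_one_at_a_time(rng):
    net = UNet2D(in_shape=(8, 8), levels=2, initial_features=4, seed=0)
    x = rng.random((5, 8, 8, 1), dtype=np.float32)
    batch = net.predict_proba(x, batch_size=5)
    single = np.concatenate([net.predict_proba(x[i:i + 1], batch_size=1)
                             for i in range(5)])
    assert np.allclose(batch, single, atol=1e-6)


def test_overfit_single_sample(rng):
    """Training on one repeated pair drives Dice near 1 quickly."""
    img = rng.random((1, 24, 24), dtype=np.float32)
    msk = np.zeros((1, 24, 24), dtype=np.float32)
    msk[0, 8:16, 6:18] = 1
    est = SliceUNet(epochs=30, batch_size=1, validation_fraction=0.5,
                    seed=0)
    est.fit(np.repeat(img, 2, axis=0), np.repeat(msk, 2, axis=0))
    pred = est.predict(img)
    assert soft_dice(pred.astype(np.float32), msk) > 0.99
    assert len(est.history_) == 30


def test_history_and_divergence_detection(rng):
    x = rng.random((8, 8, 8), dtype=np.float32)
    y = (rng.random((8, 8, 8)) > 0.5).astype(np.float32)
    est = SliceUNet(levels=2, initial_features=4, input_shape=(8, 8),
                    epochs=1, seed=0)
    est.fit(x, y)
    assert len(est.history_) == 1
    assert {"epoch", "train_loss", "val_loss", "val_dice"} <= set(
        est.history_[0])
    bad = SliceUNet(levels=2, initial_features=4, input_shape=(8, 8),
                    epochs=2, learning_rate=1e6, seed=0)
    with pytest.raises((TrainingError, FloatingPointError)):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bad.fit(x, y)


def test_checkpoint_roundtrip(tmp_path, rng):
    x = rng.random((6, 8, 8), dtype=np.float32)
    y = (rng.random((6, 8, 8)) > 0.6).astype(np.float32)
    est = SliceUNet(levels=2, initial_features=4, input_shape=(8, 8),
                    epochs=2, seed=3)
    est.fit(x, y)
    p = tmp_path / "model.npz"
    est.save(p)
    back = SliceUNet.load(p)
    assert np.allclose(back.predict_proba(x), est.predict_proba(x),
                       atol=1e-7)
    assert back.get_params()["levels"] == 2


def test_predict_slices_preserves_provenance(rng):
    from dentseg.slicer import slice_volume
    from dentseg.unet2d import predict_slices
    from dentseg.volume_io import CBCTVolume
    est = SliceUNet(levels=2, initial_features=4, input_shape=(8, 8),
                    epochs=1, seed=0)
    x = rng.random((6, 8, 8), dtype=np.float32)
    y = (rng.random((6, 8, 8)) > 0.6).astype(np.float32)
    est.fit(x, y)
    vol = CBCTVolume(rng.random((8, 8, 5)).astype(np.float32))
    stack = slice_volume(vol, axes=(2,))
    out = predict_slices(est, stack)
    assert len(out) == len(stack)  # cardinality conserved
    for rin, rout in zip(stack.records, out.records):
        assert (rout.axis, rout.index) == (rin.axis, rin.index)
        assert rout.image.shape == rin.image.shape
        assert ((rout.image > 0) & (rout.image < 1)).all()


def test_estimator_sklearn_params():
    est = SliceUNet(epochs=5)
    params = est.get_params()
    assert params["epochs"] == 5
    est.set_params(epochs=7)
    assert est.epochs == 7


# --- augmentation ----------------------------------------------------------
def test_featurewise_standardization(rng):
    imgs = rng.random((50, 24, 24), dtype=np.float32)
    aug = Augmenter(AugmentConfig(rotation_range_deg=0)).fit(imgs)
    out = aug.normalize(imgs)
    assert abs(out.mean()) < 1e-6
    assert abs(out.std() - 1) < 1e-5


def test_identity_augmenter(rng):
    cfg = AugmentConfig(center_features=False, scale_to_unit_std=False,
                        rotation_range_deg=0)
    aug = Augmenter(cfg).fit(rng.random((3, 24, 24)))
    img = rng.random((24, 24)).astype(np.float32)
    msk = rng.random((24, 24)) > 0.5
    out_i, out_m = aug.transform_pair(img, msk, np.random.default_rng(0))
    assert np.allclose(out_i, img)
    assert np.array_equal(out_m, msk)


def test_augmented_masks_stay_binary(rng):
    cfg = AugmentConfig(rotation_range_deg=90, horizontal_flip=True,
                        vertical_flip=True, shift_fraction=0.2,
                        zoom_fraction=0.2)
    aug = Augmenter(cfg).fit(rng.random((3, 24, 24)))
    msk = np.zeros((24, 24))
    msk[5:15, 8:20] = 1
    img = rng.random((24, 24)).astype(np.float32)
    g = np.random.default_rng(9)
    for _ in range(1000):
        _, m = aug.transform_pair(img, msk, g)
        assert m.dtype == bool  # re-binarised after interpolation


def test_statistics_required_before_use(rng):
    aug = Augmenter(AugmentConfig())
    with pytest.raises(RuntimeError):
        aug.normalize(rng.random((2, 24, 24)))
    with pytest.raises(ValueError):
        aug.fit(np.empty((0, 24, 24)))


# --- splitting -------------------------------------------------------------
class _Item:
    def __init__(self, cid):
        self.case_id = cid


def test_split_fraction_and_determinism():
    items = [_Item(f"c{i}") for i in range(150)]
    tr, va = split_dataset(items, fraction=0.2, unit="volume", seed=0)
    assert (len(tr), len(va)) == (120, 30)
    tr2, va2 = split_dataset(items, fraction=0.2, unit="volume", seed=0)
    assert [i.case_id for i in va] == [i.case_id for i in va2]
    tr, va = split_dataset(items[:10], fraction=0.2, seed=1)
    assert (len(tr), len(va)) == (8, 2)
    assert {i.case_id for i in tr}.isdisjoint({i.case_id for i in va})


def test_volume_split_keeps_cases_together():
    items = [_Item(f"c{i % 5}") for i in range(25)]
    tr, va = split_dataset(items, fraction=0.2, unit="volume", seed=3)
    assert {i.case_id for i in tr}.isdisjoint({i.case_id for i in va})
    assert len(tr) + len(va) == 25
    with pytest.raises(ValueError):
        split_dataset([_Item("only")], unit="volume")
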