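"""Slice-wise 2D U-Net training: augmentation, splitting, and the estimator.

The central object is :class:`SliceUNet`, a scikit-learn style estimator
(``fit`` / ``predict_proba`` / ``predict``, ``get_params`` /
``set_params``) over arrays of grayscale slices. Module-level functions
(:func:`build_unet`, :func:`make_augmenter`, :func:`split_dataset`,
:func:`fit`, :func:`predict_slices`) are thin wrappers kept for script
use.

Architecture defaults follow the reference configuration: 24 x 24 x 1
inputs, four levels realised as three pooling steps plus a bottleneck
(24 -> 12 -> 6 -> 3), two convolutions per level, 32 initial features
doubling per level, transpose-convolution upsampling with skip
concatenation, and a 1 x 1 sigmoid head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .nn import Adam, UNet2D
from .nn.losses import bce_dice_loss_and_grad, soft_dice
from .slicer import SliceStack


class TrainingError(RuntimeError):
    """Raised when optimisation diverges (non-finite loss)."""

    def __init__(self, epoch: int, message: str):
        super().__init__(f"epoch {epoch}: {message}")
        self.epoch = epoch


@dataclass
class UNetConfig:
    input_shape: tuple[int, int, int] = (24, 24, 1)
    levels: int = 4
    blocks_per_level: int = 2
    initial_features: int = 32
    kernel: int = 3


@dataclass
class AugmentConfig:
    """Featurewise standardisation + geometric augmentation settings.

    Geometric transforms are applied identically to image and mask (the
    mask re-binarised afterwards); photometric normalisation applies to
    images only. Borders are filled by reflection.
    """

    center_features: bool = True
    scale_to_unit_std: bool = True
    rotation_range_deg: float = 90.0
    horizontal_flip: bool = False
    vertical_flip: bool = False
    shift_fraction: float = 0.0
    zoom_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rotation_range_deg <= 180:
            raise ValueError("rotation_range_deg must be in [0, 180]")
        for name in ("shift_fraction", "zoom_fraction"):
            if not 0 <= getattr(self, name) <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")


@dataclass
class TrainConfig:
    epochs: int = 200
    validation_fraction: float = 0.2
    batch_size: int = 32
    loss: str = "bce_plus_dice"
    learning_rate: float = 1e-3
    seed: int = 0
    split_unit: str = "volume"  # "volume" | "slice"

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


class Augmenter:
    """Fitted augmentation stream over (image, mask) slice pairs."""

    def __init__(self, cfg: AugmentConfig):
        self.cfg = cfg
        self.mean_: float | None = None
        self.std_: float | None = None

    def fit(self, images: np.ndarray) -> "Augmenter":
        if images.size == 0:
            raise ValueError("cannot fit statistics on an empty training set")
        self.mean_ = float(np.mean(images))
        self.std_ = float(np.std(images))
        return self

    def normalize(self, images: np.ndarray) -> np.ndarray:
        if self.cfg.center_features or self.cfg.scale_to_unit_std:
            if self.mean_ is None:
                raise RuntimeError("augmenter statistics not fitted")
        out = np.asarray(images, dtype=np.float32)
        if self.cfg.center_features:
            out = out - self.mean_
        if self.cfg.scale_to_unit_std:
            out = out / (self.std_ if self.std_ > 0 else 1.0)
        return out

    def _is_geometric(self) -> bool:
        c = self.cfg
        return (c.rotation_range_deg > 0 or c.horizontal_flip
                or c.vertical_flip or c.shift_fraction > 0
                or c.zoom_fraction > 0)

    def transform_pair(self, image: np.ndarray, mask: np.ndarray,
                       rng: np.random.Generator):
        """One random geometric transform of a slice pair + normalisation."""
        img = np.asarray(image, dtype=np.float32)
        msk = np.asarray(mask, dtype=np.float32)
        c = self.cfg
        if self._is_geometric():
            h, w = img.shape
            ang = rng.uniform(-c.rotation_range_deg, c.rotation_range_deg)
            zoom = 1.0 + rng.uniform(-c.zoom_fraction, c.zoom_fraction)
            dy = rng.uniform(-c.shift_fraction, c.shift_fraction) * h
            dx = rng.uniform(-c.shift_fraction, c.shift_fraction) * w
            flip_h = c.horizontal_flip and rng.random() < 0.5
            flip_v = c.vertical_flip and rng.random() < 0.5
            th = np.deg2rad(ang)
            rot = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]]) / zoom
            if flip_v:
                rot[0] *= -1
            if flip_h:
                rot[1] *= -1
            center = np.array([(h - 1) / 2, (w - 1) / 2])
            offset = center - rot @ center + np.array([dy, dx])
            img = ndimage.affine_transform(img, rot, offset=offset, order=1,
                                           mode="reflect")
            msk = ndimage.affine_transform(msk, rot, offset=offset, order=0,
                                           mode="reflect")
        return self.normalize(img), (msk > 0.5)

    def stream(self, images: np.ndarray, masks: np.ndarray,
               seed: int | None = None):
        """Endless generator of augmented, normalised (image, mask) pairs."""
        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)
        n = len(images)
        while True:
            for i in rng.permutation(n):
                yield self.transform_pair(images[i], masks[i], rng)


def split_dataset(items, fraction: float = 0.2, unit: str = "volume",
                  seed: int = 0):
    """Disjoint, exhaustive train/validation partition.

    With ``unit="volume"`` the items are grouped by ``case_id`` (attribute
    or ``"case_id"`` key) and whole groups are assigned to one side, so no
    slices of a case leak across the split.
    """
    items = list(items)
    if unit == "volume":
        groups: dict[str, list] = {}
        for it in items:
            cid = getattr(it, "case_id", None)
            if cid is None and isinstance(it, dict):
                cid = it.get("case_id")
            if cid is None:
                raise ValueError("volume-unit split needs case_id provenance")
            groups.setdefault(cid, []).append(it)
        keys = sorted(groups)
    elif unit == "slice":
        keys = list(range(len(items)))
        groups = {i: [items[i]] for i in keys}
    else:
        raise ValueError(f"unknown split unit {unit!r}")
    if len(keys) < 2:
        raise ValueError("need at least 2 units to split")
    n_val = int(round(fraction * len(keys)))
    n_val = min(max(n_val, 1), len(keys) - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    val_keys = {keys[i] for i in order[:n_val]}
    train = [it for k in keys if k not in val_keys for it in groups[k]]
    val = [it for k in keys if k in val_keys for it in groups[k]]
    return train, val


class SliceUNet(BaseEstimator):
    """Scikit-learn style slice-segmentation estimator.

    Parameters mirror :class:`UNetConfig`, :class:`TrainConfig` and
    :class:`AugmentConfig`. ``fit`` expects ``X`` of shape (n, H, W) with
    intensities in [0, 1] and binary ``y`` of the same shape; a held-out
    validation pair may be passed explicitly, otherwise a fraction of the
    slices is split off. The epoch with the best validation loss defines
    the retained weights.

    Fitted attributes: ``net_`` (the network), ``history_`` (list of
    per-epoch records), ``augmenter_``, ``best_epoch_``.
    """

    def __init__(self, levels: int = 4, blocks_per_level: int = 2,
                 initial_features: int = 32, kernel: int = 3,
                 input_shape=(24, 24), epochs: int = 200,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 loss: str = "bce_plus_dice",
                 validation_fraction: float = 0.2,
                 augment: AugmentConfig | None = None,
                 augment_multiplier: int = 1,
                 lr_decay_milestones: tuple[float, ...] = (0.6, 0.85),
                 lr_decay_factor: float = 0.5,
                 seed: int = 0, verbose: bool = False):
        self.levels = levels
        self.blocks_per_level = blocks_per_level
        self.initial_features = initial_features
        self.kernel = kernel
        self.input_shape = input_shape
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss = loss
        self.validation_fraction = validation_fraction
        self.augment = augment
        self.augment_multiplier = augment_multiplier
        self.lr_decay_milestones = lr_decay_milestones
        self.lr_decay_factor = lr_decay_factor
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_slices, H, W)")
        if X.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"slices of shape {X.shape[1:]} do not match input_shape "
                f"{tuple(self.input_shape)}; resize slices first")
        if y is not None:
            y = (np.asarray(y) > 0.5).astype(np.float32)
            if y.shape != X.shape:
                raise ValueError("X and y shapes differ")
        return X, y

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._validate_xy(X, y)
        if X_val is None:
            n = len(X)
            n_val = max(1, int(round(self.validation_fraction * n)))
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(n)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val, y_val = self._validate_xy(X_val, y_val)

        aug_cfg = self.augment if self.augment is not None else AugmentConfig(
            rotation_range_deg=0.0)
        self.augmenter_ = Augmenter(aug_cfg).fit(X)
        self.net_ = UNet2D(in_shape=tuple(self.input_shape),
                           levels=self.levels,
                           blocks_per_level=self.blocks_per_level,
                           initial_features=self.initial_features,
                           kernel=self.kernel, seed=self.seed)
        opt = Adam(self.net_.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        Xvn = self.augmenter_.normalize(X_val)[..., None]
        yv = y_val[..., None]

        geometric = self.augmenter_._is_geometric()
        n_train = len(X)
        steps = max(1, (n_train * max(1, self.augment_multiplier))
                    // self.batch_size)
        self.history_ = []
        best = (np.inf, None, -1)
        decay_at = {int(m * self.epochs) for m in
                    (self.lr_decay_milestones or ())}
        for epoch in range(self.epochs):
            if epoch in decay_at and epoch > 0:
                opt.lr *= self.lr_decay_factor
            order = rng.permutation(n_train)
            losses = []
            pos = 0
            for _ in range(steps):
                take = min(self.batch_size, n_train)
                if pos + take > n_train:
                    order = rng.permutation(n_train)
                    pos = 0
                idx = order[pos:pos + take]
                pos += take
                if geometric:
                    pairs = [self.augmenter_.transform_pair(X[i], y[i], rng)
                             for i in idx]
                    xb = np.stack([p[0] for p in pairs])[..., None]
                    yb = np.stack([p[1] for p in pairs]).astype(
                        np.float32)[..., None]
                else:
                    xb = self.augmenter_.normalize(X[idx])[..., None]
                    yb = y[idx][..., None]
                z = self.net_.forward(xb, train=True)
                loss, grad = bce_dice_loss_and_grad(z, yb, self.loss)
                if not np.isfinite(loss):
                    raise TrainingError(epoch, f"non-finite loss {loss}")
                self.net_.backward(grad)
                opt.step()
                losses.append(loss)
            val_loss, val_dice = self._evaluate(Xvn, yv)
            rec = dict(epoch=epoch, train_loss=float(np.mean(losses)),
                       val_loss=val_loss, val_dice=val_dice)
            self.history_.append(rec)
            if self.verbose:
                print(f"epoch {epoch:3d}  train {rec['train_loss']:.4f}  "
                      f"val {val_loss:.4f}  dice {val_dice:.4f}")
            if val_loss < best[0]:
                best = (val_loss, self.net_.get_weights(), epoch)
        if best[1] is not None:
            self.net_.set_weights(best[1])
        self.best_epoch_ = best[2]
        return self

    def _evaluate(self, Xn, y1, batch_size: int = 64):
        losses, dices = [], []
        for i in range(0, len(Xn), batch_size):
            z = self.net_.forward(Xn[i:i + batch_size])
            loss, _ = bce_dice_loss_and_grad(z, y1[i:i + batch_size],
                                             self.loss)
            from .nn.losses import sigmoid
            p = sigmoid(z)
            dices.append(soft_dice(p >= 0.5, y1[i:i + batch_size]))
            losses.append(loss)
        return float(np.mean(losses)), float(np.mean(dices))

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        X, _ = self._validate_xy(X, None)
        Xn = self.augmenter_.normalize(X)[..., None]
        return self.net_.predict_proba(Xn)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(X) >= threshold

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint with the config embedded."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        path = Path(path)
        meta = dict(params=self.get_params(deep=False),
                    net=self.net_.config_dict(),
                    augment_stats=dict(mean=self.augmenter_.mean_,
                                       std=self.augmenter_.std_),
                    best_epoch=self.best_epoch_)
        meta["params"]["augment"] = (asdict(self.augment)
                                     if self.augment else None)
        meta["params"]["lr_decay_milestones"] = list(
            self.lr_decay_milestones or ())
        arrays = {f"w{i}": w for i, w in enumerate(self.net_.get_weights())}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SliceUNet":
        with np.load(Path(path), allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            weights = [npz[f"w{i}"]
                       for i in range(len(npz.files) - 1)]
        params = meta["params"]
        if params.get("augment") is not None:
            params["augment"] = AugmentConfig(**params["augment"])
        params["input_shape"] = tuple(params["input_shape"])
        est = cls(**params)
        est.net_ = UNet2D.from_config(meta["net"])
        est.net_.set_weights(weights)
        aug_cfg = est.augment if est.augment is not None else AugmentConfig(
            rotation_range_deg=0.0)
        est.augmenter_ = Augmenter(aug_cfg)
        est.augmenter_.mean_ = meta["augment_stats"]["mean"]
        est.augmenter_.std_ = meta["augment_stats"]["std"]
        est.history_ = []
        est.best_epoch_ = meta["best_epoch"]
        return est

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history_)


# --- thin functional wrappers ---------------------------------------------
def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet2D:
    cfg = cfg or UNetConfig()
    h, w = cfg.input_shape[:2]
    return UNet2D(in_shape=(h, w), in_channels=cfg.input_shape[2],
                  levels=cfg.levels, blocks_per_level=cfg.blocks_per_level,
                  initial_features=cfg.initial_features, kernel=cfg.kernel,
                  seed=seed)


def make_augmenter(cfg: AugmentConfig, training_images) -> Augmenter:
    return Augmenter(cfg).fit(np.asarray(training_images, dtype=np.float32))


def fit(model: SliceUNet, X, y, X_val=None, y_val=None) -> SliceUNet:
    return model.fit(X, y, X_val=X_val, y_val=y_val)


def predict_slices(model: SliceUNet, stack: SliceStack) -> SliceStack:
    """Per-record probability images with provenance preserved."""
    from dataclasses import replace as _replace
    X = np.stack([r.image for r in stack.records]).astype(np.float32)
    probs = model.predict_proba(X)
    records = [_replace(r, image=probs[i], is_mask=False)
               for i, r in enumerate(stack.records)]
    return SliceStack(records, stack.source_shape, stack.spacing_mm)
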