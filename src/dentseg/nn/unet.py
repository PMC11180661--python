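"""2D U-Net assembled from the primitive layers.

Architecture (defaults): four resolution levels realised as three 2x2
poolings plus a bottleneck, two 3x3 conv+ReLU blocks per level, 32 initial
feature channels doubling per level (32, 64, 128, 256), stride-2 transpose
convolutions (zero-stuffing + same-padding conv) with ReLU on the way up,
skip concatenation at every level, and a 1x1 convolution + sigmoid head.
Output spatial shape equals input spatial shape with one channel.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, MaxPool2, ReLU, UpsampleZero2
from .losses import sigmoid


class _Block:
    """blocks_per_level x (conv k x k + ReLU)."""

    def __init__(self, cin, cout, n, k, rng, dtype):
        self.layers = []
        c = cin
        for _ in range(n):
            self.layers.append(Conv2D(c, cout, k, rng, dtype))
            self.layers.append(ReLU())
            c = cout

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]


class UNet2D:
    """Encoder-decoder segmentation network returning logits.

    Parameters
    ----------
    in_shape : (H, W) input spatial extents; each must be divisible by
        ``2 ** (levels - 1)`` (the number of pooling steps).
    levels : resolution levels including the bottleneck (default 4).
    blocks_per_level : convolutions per level (default 2).
    initial_features : channels at the top level; level ``l`` carries
        ``initial_features * 2**l`` channels.
    kernel : odd convolution kernel size (default 3).
    """

    def __init__(self, in_shape=(24, 24), in_channels: int = 1,
                 levels: int = 4, blocks_per_level: int = 2,
                 initial_features: int = 32, kernel: int = 3,
                 seed: int = 0, dtype=np.float32):
        h, w = in_shape
        pools = levels - 1
        if h % (1 << pools) or w % (1 << pools):
            raise ValueError(
                f"input extents {in_shape} not divisible by 2^{pools}; "
                f"reduce levels or pad the input")
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.in_shape = (h, w)
        self.in_channels = in_channels
        self.levels = levels
        self.blocks_per_level = blocks_per_level
        self.initial_features = initial_features
        self.kernel = kernel
        self.seed = seed
        self.dtype = dtype

        rng = np.random.default_rng(seed)
        feats = [initial_features * (1 << l) for l in range(levels)]
        self.feature_widths = feats

        self.enc = []
        c = in_channels
        for l in range(levels - 1):
            self.enc.append(_Block(c, feats[l], blocks_per_level, kernel,
                                   rng, dtype))
            c = feats[l]
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.bottom = _Block(c, feats[-1], blocks_per_level, kernel, rng,
                             dtype)

        self.ups = []       # (UpsampleZero2, Conv2D, ReLU) per decoder level
        self.dec = []
        c = feats[-1]
        for l in reversed(range(levels - 1)):
            self.ups.append((UpsampleZero2(), Conv2D(c, feats[l], kernel,
                                                     rng, dtype), ReLU()))
            self.dec.append(_Block(feats[l] * 2, feats[l], blocks_per_level,
                                   kernel, rng, dtype))
            c = feats[l]
        self.head = Conv2D(c, 1, 1, rng, dtype)
        self._skip_channels = None

    @property
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params
        out += self.bottom.params
        for (_, conv, _), blk in zip(self.ups, self.dec):
            out += conv.params + blk.params
        out += self.head.params
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of NHWC images (C = in_channels)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottom.forward(x)
        for (up, conv, act), blk, skip in zip(self.ups, self.dec,
                                              reversed(skips)):
            x = act.forward(conv.forward(up.forward(x)))
            x = np.concatenate([skip, x], axis=-1)
            x = blk.forward(x)
        self._skip_channels = [s.shape[-1] for s in skips]
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = [None] * len(self.enc)
        for i in reversed(range(len(self.dec))):
            (up, conv, act), blk = self.ups[i], self.dec[i]
            dy = blk.backward(dy)
            l = len(self.enc) - 1 - i  # encoder level this decoder mirrors
            csk = self._skip_channels[l]
            dskips[l] = dy[..., :csk]
            dy = up.backward(conv.backward(act.backward(dy[..., csk:])))
        dy = self.bottom.backward(dy)
        for blk, pool, dsk in zip(reversed(self.enc), reversed(self.pools),
                                  reversed(dskips)):
            dy = pool.backward(dy) + dsk
            dy = blk.backward(dy)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid probabilities, batched; returns (N, H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        out = np.empty(x.shape[:3], dtype=self.dtype)
        for i in range(0, x.shape[0], batch_size):
            z = self.forward(x[i:i + batch_size])
            out[i:i + batch_size] = sigmoid(z)[..., 0]
        return out

    # --- weight (de)serialisation -------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def set_weights(self, weights) -> None:
        own = self.params
        if len(weights) != len(own):
            raise ValueError("weight list does not match architecture")
        for (p, _), w in zip(own, weights):
            p[...] = w

    def config_dict(self) -> dict:
        return dict(in_shape=list(self.in_shape),
                    in_channels=self.in_channels, levels=self.levels,
                    blocks_per_level=self.blocks_per_level,
                    initial_features=self.initial_features,
                    kernel=self.kernel, seed=self.seed)

    @classmethod
    def from_config(cls, cfg: dict, dtype=np.float32) -> "UNet2D":
        cfg = dict(cfg)
        cfg["in_shape"] = tuple(cfg["in_shape"])
        return cls(dtype=dtype, **cfg)
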