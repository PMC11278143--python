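"""Residual U-net for 2.5D slice segmentation.

Encoder–decoder with 5 levels.  Each level applies two padded 3×3 stride-1
convolutions, each followed by batch normalization and PReLU, with an
additive residual shortcut across the convolution pair (identity when the
channel counts match, a 1×1 projection otherwise), then channel dropout.
Downsampling is 2×2 average pooling; feature channels double as spatial
dimensions halve.  The bottleneck width is parameterized directly (1000
filters at the reference 240×240 scale).  The decoder upsamples by
nearest-neighbour 2× (avoiding transposed-convolution checkerboard
artifacts), concatenates the matching encoder features, and applies the same
residual double-convolution block.  A 1×1 convolution plus sigmoid produces
a per-pixel foreground probability, thresholded at 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, AvgPool2x2, BatchNorm2d, Conv2d, Dropout2d, Layer,
                 PReLU, UpsampleNearest2x)
from .pseudo_rgb import PseudoRGBSlice

__all__ = ["ResUnetConfig", "ResUNet", "ConvBlock", "build_model",
           "predict_proba", "binarize"]


@dataclass
class ResUnetConfig:
    """Architecture hyperparameters.

    ``base_filters`` sets the first level's channel count; levels double it
    until the bottleneck, whose width is overridden by ``bottleneck_filters``
    (1000 at the reference scale — only the bottleneck width is prescribed,
    the doubling rule fixes the earlier ratios).  ``in_shape`` is (H, W, 3);
    H and W must be divisible by 2^(levels−1).
    """

    in_shape: tuple = (240, 240, 3)
    levels: int = 5
    base_filters: int = 64
    bottleneck_filters: int = 1000
    dropout_p: float = 0.6
    prob_threshold: float = 0.5

    def __post_init__(self):
        h, w = self.in_shape[0], self.in_shape[1]
        factor = 2 ** (self.levels - 1)
        if h % factor or w % factor:
            raise ValueError(
                f"spatial dims {h}×{w} must be divisible by 2^(levels-1)={factor}")
        if len(self.in_shape) != 3 or self.in_shape[2] != 3:
            raise ValueError(f"in_shape must be (H, W, 3), got {self.in_shape}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0,1), got {self.dropout_p}")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0,1)")

    @property
    def encoder_channels(self) -> list:
        """Channel counts of the levels above the bottleneck."""
        return [self.base_filters * 2 ** i for i in range(self.levels - 1)]


class ConvBlock(Layer):
    """conv→BN→PReLU→conv→BN, additive shortcut, PReLU, channel dropout."""

    def __init__(self, cin: int, cout: int, dropout_p: float,
                 rng: np.random.Generator, name: str):
        self.conv1 = Conv2d(cin, cout, 3, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2d(cout, name=f"{name}.bn1")
        self.act1 = PReLU(cout, name=f"{name}.act1")
        self.conv2 = Conv2d(cout, cout, 3, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2d(cout, name=f"{name}.bn2")
        self.act2 = PReLU(cout, name=f"{name}.act2")
        self.proj = Conv2d(cin, cout, 1, rng, f"{name}.proj") if cin != cout else None
        self.drop = Dropout2d(dropout_p, rng)

    def parameters(self):
        layers = [self.conv1, self.bn1, self.act1, self.conv2, self.bn2, self.act2]
        if self.proj is not None:
            layers.append(self.proj)
        return [p for l in layers for p in l.parameters()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.act1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        sc = x if self.proj is None else self.proj.forward(x, train)
        out = self.act2.forward(h + sc, train)
        return self.drop.forward(out, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.drop.backward(dy)
        dsum = self.act2.backward(dy)
        dh = self.bn2.backward(dsum)
        dh = self.conv2.backward(dh)
        dh = self.conv1.backward(self.bn1.backward(self.act1.backward(dh)))
        dsc = dsum if self.proj is None else self.proj.backward(dsum)
        return dh + dsc


class ResUNet:
    """The full network; deterministic for a fixed config and seed."""

    def __init__(self, cfg: ResUnetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = cfg.encoder_channels
        self.enc = []
        cin = 3
        for i, c in enumerate(chans):
            self.enc.append(ConvBlock(cin, c, cfg.dropout_p, rng, f"enc{i}"))
            cin = c
        self.pool = AvgPool2x2()
        self.bottleneck = ConvBlock(cin, cfg.bottleneck_filters, cfg.dropout_p,
                                    rng, "bottleneck")
        self.up = UpsampleNearest2x()
        self.dec = []
        cprev = cfg.bottleneck_filters
        for i in reversed(range(len(chans))):
            self.dec.append(ConvBlock(cprev + chans[i], chans[i], cfg.dropout_p,
                                      rng, f"dec{i}"))
            cprev = chans[i]
        self.head = Conv2d(cprev, 1, 1, rng, "head")
        self._cache = None

    def parameters(self) -> list:
        params = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            params.extend(blk.parameters())
        params.extend(self.head.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 3, H, W) → per-pixel probabilities (N, 1, H, W)."""
        skips = []
        for blk in self.enc:
            x = blk.forward(x, train)
            skips.append(x)
            x = self.pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for blk, skip in zip(self.dec, reversed(skips)):
            x = self.up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        logits = self.head.forward(x, train)
        prob = 1.0 / (1.0 + np.exp(-logits))
        if train:
            self._cache = prob
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability) through the whole net."""
        prob = self._cache
        dy = dprob * prob * (1.0 - prob)        # through the sigmoid
        dy = self.head.backward(dy)
        dskips = [None] * len(self.dec)
        for i in reversed(range(len(self.dec))):
            dy = self.dec[i].backward(dy)
            csk = self._skip_channels[i]
            dskips[i] = dy[:, :csk]
            dy = self.up.backward(dy[:, csk:])
        dy = self.bottleneck.backward(dy)
        # encoder i's skip gradient pairs with decoder len-1-i
        for i in reversed(range(len(self.enc))):
            dy = self.pool.backward(dy)
            dy = dy + dskips[len(self.dec) - 1 - i]
            dy = self.enc[i].backward(dy)

    def get_weights(self) -> list:
        """Snapshot all parameters and batch-norm running statistics."""
        state = [p.value.copy() for p in self.parameters()]
        for blk in self.enc + [self.bottleneck] + self.dec:
            for l in (blk.bn1, blk.bn2):
                state.append(l.running_mean.copy())
                state.append(l.running_var.copy())
        return state

    def set_weights(self, state: list) -> None:
        params = self.parameters()
        for p, v in zip(params, state[:len(params)]):
            p.value = v.copy()
        i = len(params)
        for blk in self.enc + [self.bottleneck] + self.dec:
            for l in (blk.bn1, blk.bn2):
                l.running_mean = state[i].copy()
                l.running_var = state[i + 1].copy()
                i += 2

    def save(self, path) -> None:
        state = self.get_weights()
        np.savez_compressed(path, *state)

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


def build_model(cfg: ResUnetConfig, seed: int = 0) -> ResUNet:
    """Construct a network; identical config+seed gives identical weights."""
    return ResUNet(cfg, seed=seed)


def _to_batch(slices) -> np.ndarray:
    arrs = []
    for s in slices:
        data = s.data if isinstance(s, PseudoRGBSlice) else np.asarray(s)
        arrs.append(np.transpose(data, (2, 0, 1)))  # HWC → CHW
    return np.stack(arrs).astype(np.float64)


def predict_proba(net: ResUNet, slices, batch_size: int = 16) -> np.ndarray:
    """Inference-mode probabilities, shape (N, H, W)."""
    batch = _to_batch(slices)
    h, w = batch.shape[2], batch.shape[3]
    exp_h, exp_w = net.cfg.in_shape[0], net.cfg.in_shape[1]
    if (h, w) != (exp_h, exp_w):
        raise ValueError(f"input spatial shape {(h, w)} != config {(exp_h, exp_w)}")
    out = []
    for i in range(0, len(batch), batch_size):
        prob = net.forward(batch[i:i + batch_size], train=False)
        out.append(prob[:, 0])
    return np.concatenate(out, axis=0)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel = 1 iff probability ≥ threshold."""
    return (np.asarray(p) >= threshold).astype(np.uint8)
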