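"""Network assemblies: the 3-level U-Net generator and the conditional
convolutional discriminator.

Both expose ``forward(x, training)``, ``backward(grad)`` (which accumulates
parameter gradients and returns the input gradient) and ``params()``; weight
initialization is driven by an explicit seeded generator so runs are
reproducible.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    LeakyReLU,
    MaxPool2d,
    ReLU,
    Sigmoid,
)

__all__ = ["Sequential", "UNetGenerator", "PatchDiscriminator"]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training: bool = True):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def _conv_block(c_in: int, c_out: int, rng) -> Sequential:
    """3x3 same-padded conv + batch norm + ReLU."""
    return Sequential(Conv2d(c_in, c_out, 3, pad=1, rng=rng),
                      BatchNorm2d(c_out), ReLU())


class UNetGenerator(Layer):
    """Three-level encoder-decoder with skip connections and sigmoid output.

    Encoder channel progression ``1 -> c -> 2c -> 4c`` with 2x2 max pooling
    between levels; the bottleneck conv doubles once more to ``8c`` (512 at
    the default ``c = 64``), so a 128 x 1024 input reaches a 512-channel
    16 x 128 bottleneck.  The decoder mirrors the encoder with 2x2 stride-2
    transposed convolutions and concatenation skips; a final 3x3 conv and
    sigmoid map back to one channel in (0, 1).
    """

    def __init__(self, base_channels: int = 64, in_channels: int = 1,
                 max_channels: int = 512, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_channels
        ch = [min(c * 2**i, max_channels) for i in range(4)]  # level widths
        self.channels = ch
        self.enc = [
            _conv_block(in_channels, ch[0], rng),
            _conv_block(ch[0], ch[1], rng),
            _conv_block(ch[1], ch[2], rng),
        ]
        self.pools = [MaxPool2d() for _ in range(3)]
        self.bottleneck = _conv_block(ch[2], ch[3], rng)
        self.ups = [
            ConvTranspose2d(ch[3], ch[2], rng=rng),
            ConvTranspose2d(ch[2], ch[1], rng=rng),
            ConvTranspose2d(ch[1], ch[0], rng=rng),
        ]
        self.dec = [
            _conv_block(2 * ch[2], ch[2], rng),
            _conv_block(2 * ch[1], ch[1], rng),
            _conv_block(2 * ch[0], ch[0], rng),
        ]
        self.out_conv = Conv2d(ch[0], 1, 3, pad=1, rng=rng)
        self.out_act = Sigmoid()

    def params(self):
        mods = (*self.enc, self.bottleneck, *self.ups, *self.dec,
                self.out_conv)
        return [p for m in mods for p in m.params()]

    # -- forward -------------------------------------------------------
    def encode(self, x: np.ndarray, training: bool = False):
        """Run the encoder only; returns (bottleneck features, skips)."""
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        return self.bottleneck.forward(h, training), skips

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("generator expects NCHW input with 1 channel")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("spatial dimensions must be divisible by 8")
        h, skips = self.encode(x, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, training)
            h = dec.forward(np.concatenate([h, skip], axis=1), training)
        return self.out_act.forward(self.out_conv.forward(h, training), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_conv.backward(self.out_act.backward(grad))
        skip_grads = []
        for up, dec, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                   self._skip_channels):
            g = dec.backward(g)
            g_up, g_skip = g[:, :-c_skip], g[:, -c_skip:]
            skip_grads.append(g_skip)
            g = up.backward(g_up)
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallow-first; the encoder unwinds deep-first
        for pool, enc, g_skip in zip(reversed(self.pools), reversed(self.enc),
                                     reversed(skip_grads)):
            g = pool.backward(g)
            g = enc.backward(g + g_skip)
        return g


class PatchDiscriminator(Layer):
    """Five-layer conditional convolutional classifier.

    Operates on the channel-concatenated (input, candidate output) pair.
    Layers 1-4 are 4x4 stride-2 convolutions, each followed by batch
    normalization and LeakyReLU; layer 5 is a 4x4 stride-1 same-padded
    convolution to one channel followed by a sigmoid, yielding a patch
    probability map in (0, 1).
    """

    N_CONV_LAYERS = 5

    def __init__(self, in_channels: int = 2, base_channels: int = 64,
                 max_channels: int = 512, seed: int = 0):
        rng = np.random.default_rng(seed)
        ch = [min(base_channels * 2**i, max_channels) for i in range(4)]
        layers: list[Layer] = []
        c_prev = in_channels
        for c in ch:
            layers += [Conv2d(c_prev, c, 4, stride=2, pad=1, rng=rng),
                       BatchNorm2d(c), LeakyReLU(0.2)]
            c_prev = c
        layers += [Conv2d(c_prev, 1, 4, stride=1, pad=(1, 2, 1, 2), rng=rng),
                   Sigmoid()]
        self.net = Sequential(*layers)

    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, Conv2d) for l in self.net.layers)

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("spatial dimensions must be divisible by 16")
        return self.net.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)
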