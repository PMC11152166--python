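"""Residual blocks and a sequential network container."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv2D,
    Layer,
    Param,
    PointwiseConv3D,
    ReLU,
    SpatialConv3D,
    TemporalConv3D,
)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w


class _ResidualBase(Layer):
    """Main path plus identity/projection shortcut with additive merge."""

    def __init__(self, main: list[Layer], shortcut: list[Layer] | None, post_relu: bool):
        self.main = Sequential(main)
        self.shortcut = Sequential(shortcut) if shortcut is not None else None
        self.post_relu = ReLU() if post_relu else None

    def params(self):
        out = self.main.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x, training=False):
        y = self.main.forward(x, training)
        s = self.shortcut.forward(x, training) if self.shortcut is not None else x
        out = y + s
        if self.post_relu is not None:
            out = self.post_relu.forward(out, training)
        return out

    def backward(self, dout):
        if self.post_relu is not None:
            dout = self.post_relu.backward(dout)
        dx = self.main.backward(dout)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dout)
        else:
            dx = dx + dout
        return dx


def mid_channels(policy: str, t_kernel: int, s_kernel: int, cin: int, cout: int) -> int:
    """Width of the intermediate features between the spatial and temporal half.

    ``equal_to_out`` uses the output width; ``matched_3d`` matches the
    parameter budget of a full 3D convolution of the same kernel.
    """
    if policy == "equal_to_out":
        return cout
    if policy == "matched_3d":
        d2 = s_kernel * s_kernel
        return max(1, (t_kernel * d2 * cin * cout) // (d2 * cin + t_kernel * cout))
    raise ValueError(f"unknown mid_channel_policy: {policy!r}")


class ResBlock21D(_ResidualBase):
    """(2+1)D residual block.

    Two ``[spatial 1xkxk -> BN -> ReLU -> temporal kx1x1 -> BN -> ReLU]``
    brackets with an additive shortcut at the end; a stride-2 block
    downsamples frames, height and width in its leading convolution and
    projects the shortcut with a strided 1x1x1 convolution.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        cin: int,
        filters: int,
        stride: int,
        spatial_kernel: int = 3,
        temporal_kernel: int = 3,
        mid_channel_policy: str = "equal_to_out",
    ):
        f = filters
        m1 = mid_channels(mid_channel_policy, temporal_kernel, spatial_kernel, cin, f)
        m2 = mid_channels(mid_channel_policy, temporal_kernel, spatial_kernel, f, f)
        main: list[Layer] = [
            SpatialConv3D(rng, spatial_kernel, cin, m1, stride=stride, t_stride=stride),
            BatchNorm(m1),
            ReLU(),
            TemporalConv3D(rng, temporal_kernel, m1, f, 1),
            BatchNorm(f),
            ReLU(),
            SpatialConv3D(rng, spatial_kernel, f, m2),
            BatchNorm(m2),
            ReLU(),
            TemporalConv3D(rng, temporal_kernel, m2, f, 1),
            BatchNorm(f),
            ReLU(),
        ]
        shortcut = None
        if stride != 1 or cin != f:
            shortcut = [PointwiseConv3D(rng, cin, f, (stride, stride, stride)), BatchNorm(f)]
        super().__init__(main, shortcut, post_relu=False)


class ResBlock2D(_ResidualBase):
    """Standard 2D basic block (two 3x3 convolutions, post-add ReLU)."""

    def __init__(self, rng: np.random.Generator, cin: int, filters: int, stride: int):
        f = filters
        main: list[Layer] = [
            Conv2D(rng, 3, cin, f, stride),
            BatchNorm(f),
            ReLU(),
            Conv2D(rng, 3, f, f, 1),
            BatchNorm(f),
        ]
        shortcut = None
        if stride != 1 or cin != f:
            shortcut = [_StridedPointwise2D(rng, cin, f, stride), BatchNorm(f)]
        super().__init__(main, shortcut, post_relu=True)


class _StridedPointwise2D(Layer):
    """1x1 projection convolution for 2D shortcuts."""

    def __init__(self, rng, cin, cout, stride):
        self._p = PointwiseConv3D(rng, cin, cout, (1, stride, stride))

    def params(self):
        return self._p.params()

    def forward(self, x, training=False):
        return self._p.forward(x[:, None], training)[:, 0]

    def backward(self, dout):
        return self._p.backward(dout[:, None])[:, 0]
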