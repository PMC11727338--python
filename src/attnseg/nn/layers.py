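"""Building blocks of the attention U-Net: conv blocks, spatial attention, decoder."""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Conv2d:
    """Same-padded stride-1 convolution with He-uniform initialised weights."""

    def __init__(self, f_in: int, f_out: int, kernel: int, rng: np.random.Generator):
        fan_in = f_in * kernel * kernel
        bound = math.sqrt(6.0 / fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(f_out, f_in, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(f_out), requires_grad=True)
        self.f_in, self.f_out, self.kernel = f_in, f_out, kernel

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]

    def param_count(self) -> int:
        return self.weight.data.size + self.bias.data.size


class ConvBlock:
    """Triple 3x3 convolution: conv -> ReLU -> conv -> ReLU -> conv.

    Channels go f_in -> f_out at the first convolution and stay at f_out.
    ReLU sits between the convolutions, not after the last one.  An optional
    residual add (1x1 projection when channel counts differ) is off by default.
    """

    def __init__(
        self,
        f_in: int,
        f_out: int,
        rng: np.random.Generator,
        residual: bool = False,
    ):
        self.convs = [
            Conv2d(f_in, f_out, 3, rng),
            Conv2d(f_out, f_out, 3, rng),
            Conv2d(f_out, f_out, 3, rng),
        ]
        self.residual = residual
        self.proj = None
        if residual and f_in != f_out:
            self.proj = Conv2d(f_in, f_out, 1, rng)
        self.f_in, self.f_out = f_in, f_out

    def __call__(self, x: Tensor) -> Tensor:
        y = self.convs[0](x)
        y = ad.relu(y)
        y = self.convs[1](y)
        y = ad.relu(y)
        y = self.convs[2](y)
        if self.residual:
            shortcut = self.proj(x) if self.proj is not None else x
            y = ad.add(y, shortcut)
        return y

    def parameters(self) -> list[Tensor]:
        params = [p for c in self.convs for p in c.parameters()]
        if self.proj is not None:
            params += self.proj.parameters()
        return params


class SpatialAttentionBlock:
    """Spatial attention gate doubling the channel count (C -> 2C).

    Gate path: channel-concat of window average- and max-pooled input
    (2C channels) -> 1x1 conv (2C -> 2C) -> sigmoid.  Value path: window
    max-pooled input -> 1x1 conv (C -> 2C).  Output is the elementwise
    product; spatial dims shrink by the pool factor.  Setting
    ``force_open`` bypasses the gate (gate == 1 everywhere), which turns
    the block into a plain pooled projection — the ablation hook.
    """

    def __init__(self, c_in: int, rng: np.random.Generator, pool: int = 2):
        self.c_in = c_in
        self.c_out = 2 * c_in
        self.pool = pool
        self.gate_conv = Conv2d(2 * c_in, 2 * c_in, 1, rng)
        self.value_conv = Conv2d(c_in, 2 * c_in, 1, rng)
        self.force_open = False
        self.last_gate_: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.c_in:
            raise ValueError(
                f"attention block expects {self.c_in} channels, got {x.data.shape[1]}"
            )
        pooled_avg = ad.avgpool2d(x, self.pool)
        pooled_max = ad.maxpool2d(x, self.pool)
        value = self.value_conv(pooled_max)
        if self.force_open:
            self.last_gate_ = np.ones_like(value.data)
            return value
        gate = ad.sigmoid(self.gate_conv(ad.concat([pooled_avg, pooled_max])))
        self.last_gate_ = gate.data
        return ad.mul(gate, value)

    def parameters(self) -> list[Tensor]:
        return self.gate_conv.parameters() + self.value_conv.parameters()


class DecoderBlock:
    """Nearest-neighbour upsample, skip concatenation, triple-conv refinement."""

    def __init__(
        self,
        f_in_total: int,
        f_out: int,
        up_factor: int,
        rng: np.random.Generator,
        residual: bool = False,
    ):
        self.up_factor = up_factor
        self.block = ConvBlock(f_in_total, f_out, rng, residual=residual)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        up = ad.upsample_nearest(x, self.up_factor)
        if up.data.shape[2:] != skip.data.shape[2:]:
            raise ValueError(
                f"decoder resolution mismatch: upsampled {up.data.shape[2:]} "
                f"vs skip {skip.data.shape[2:]}"
            )
        return self.block(ad.concat([up, skip]))

    def parameters(self) -> list[Tensor]:
        return self.block.parameters()
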