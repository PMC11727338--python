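"""The spatial-attention U-Net.

Layer plan (base width 16, channel counts at block boundaries):

    encoder   FP1(16) -> FSA1(32, /2) -> FP2(32, /4) -> FP3(64)
              -> FSA2(128, /2) -> FP4(128, /4) -> FP5 bottleneck(256)
    decoder   x4 -> 128, x2 -> 64, x4 -> 32, x2 -> 16, 3x3 head, sigmoid

FP blocks are triple 3x3 convolutions with interleaved ReLU; FSA blocks are
spatial attention gates that double the channel count while halving the
resolution; the two stride-4 max-pools after FP2/FP4 complete a total
downsampling factor of 2*4*2*4 = 64, mirrored by decoder upsample factors
[4, 2, 4, 2].  Skip connections feed [FP1, FSA1, FP3, FSA2] to the decoder
stages of matching resolution.  The head is a 3x3 conv to ``out_channels``
followed by a sigmoid, giving per-pixel foreground probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import ConvBlock, Conv2d, DecoderBlock, SpatialAttentionBlock


@dataclass
class NetworkCfg:
    """Architecture hyper-parameters.

    ``base_width`` scaled by ``width_multiplier`` gives the first block's
    channel count c1; every other width is a fixed multiple of c1
    (encoder [c1, 2c1, 2c1, 4c1, 8c1, 8c1, 16c1], decoder
    [8c1, 4c1, 2c1, c1]), so the default (16, 1.0) reproduces the
    16/32/32/64/128/128/256 plan while small multipliers give desk-scale
    networks with identical topology.
    """

    in_channels: int = 3
    out_channels: int = 1
    base_width: int = 16
    width_multiplier: float = 1.0
    attention_pool: int = 2
    encoder_pool: int = 4
    residual: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.width() < 1:
            raise ValueError("base_width * width_multiplier must round to >= 1")

    def width(self) -> int:
        return max(1, round(self.base_width * self.width_multiplier))

    @property
    def pool_factors(self) -> list[int]:
        return [self.attention_pool, self.encoder_pool] * 2

    @property
    def upsample_factors(self) -> list[int]:
        return [self.encoder_pool, self.attention_pool] * 2

    @property
    def divisor(self) -> int:
        return int(np.prod(self.pool_factors))

    @property
    def encoder_widths(self) -> list[int]:
        c = self.width()
        return [c, 2 * c, 2 * c, 4 * c, 8 * c, 8 * c, 16 * c]

    @property
    def decoder_widths(self) -> list[int]:
        c = self.width()
        return [8 * c, 4 * c, 2 * c, c]


class AttentionUNet:
    """Encoder–decoder segmentation network with spatial attention gates."""

    def __init__(self, cfg: NetworkCfg | None = None, **kwargs):
        self.cfg = cfg if cfg is not None else NetworkCfg(**kwargs)
        c = self.cfg.width()
        rng = np.random.default_rng(self.cfg.seed)
        res = self.cfg.residual
        self.enc1 = ConvBlock(self.cfg.in_channels, c, rng, residual=res)
        self.att1 = SpatialAttentionBlock(c, rng, pool=self.cfg.attention_pool)
        self.enc2 = ConvBlock(2 * c, 2 * c, rng, residual=res)
        self.enc3 = ConvBlock(2 * c, 4 * c, rng, residual=res)
        self.att2 = SpatialAttentionBlock(4 * c, rng, pool=self.cfg.attention_pool)
        self.enc4 = ConvBlock(8 * c, 8 * c, rng, residual=res)
        self.bottleneck = ConvBlock(8 * c, 16 * c, rng, residual=res)
        up = self.cfg.upsample_factors
        # decoder input channels: upsampled features + skip
        self.dec = [
            DecoderBlock(16 * c + 8 * c, 8 * c, up[0], rng, residual=res),
            DecoderBlock(8 * c + 4 * c, 4 * c, up[1], rng, residual=res),
            DecoderBlock(4 * c + 2 * c, 2 * c, up[2], rng, residual=res),
            DecoderBlock(2 * c + c, c, up[3], rng, residual=res),
        ]
        self.head = Conv2d(c, self.cfg.out_channels, 3, rng)

    # ------------------------------------------------------------- plumbing
    def _modules(self):
        return [
            ("FP1", self.enc1),
            ("FSA1", self.att1),
            ("FP2", self.enc2),
            ("FP3", self.enc3),
            ("FSA2", self.att2),
            ("FP4", self.enc4),
            ("FP5", self.bottleneck),
            ("D1", self.dec[0]),
            ("D2", self.dec[1]),
            ("D3", self.dec[2]),
            ("D4", self.dec[3]),
            ("head", self.head),
        ]

    def parameters(self) -> list[Tensor]:
        return [p for _, m in self._modules() for p in m.parameters()]

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter p{i} shape mismatch")
            p.data = arr.copy()

    def set_gate_override(self, force_open: bool) -> None:
        """Force both attention gates to 1 (ablation: attention disabled)."""
        self.att1.force_open = force_open
        self.att2.force_open = force_open

    # -------------------------------------------------------------- forward
    def _validate_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4:
            raise ValueError("input must be (N,C,H,W) or (C,H,W)")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        d = self.cfg.divisor
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} must be divisible by {d} "
                f"(product of the pooling factors {self.cfg.pool_factors})"
            )
        return x

    def encoder_forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Run the contracting path; returns (FP4, skips [FP1, FSA1, FP3, FSA2])."""
        fp1 = self.enc1(x)
        fsa1 = self.att1(fp1)
        fp2 = ad.maxpool2d(self.enc2(fsa1), self.cfg.encoder_pool)
        fp3 = self.enc3(fp2)
        fsa2 = self.att2(fp3)
        fp4 = ad.maxpool2d(self.enc4(fsa2), self.cfg.encoder_pool)
        return fp4, [fp1, fsa1, fp3, fsa2]

    def forward(self, x) -> Tensor:
        """Full forward pass; returns per-pixel probabilities in (0,1)."""
        if not isinstance(x, Tensor):
            x = Tensor(self._validate_input(x))
        else:
            self._validate_input(x.data)
        fp4, skips = self.encoder_forward(x)
        y = self.bottleneck(fp4)
        for block, skip in zip(self.dec, reversed(skips)):
            y = block(y, skip)
        return ad.sigmoid(self.head(y))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (no gradient graph)."""
        with ad.no_grad():
            return self.forward(x).data

    __call__ = forward

    # -------------------------------------------------------------- summary
    def summary(self, input_size: int = 512) -> list[dict]:
        """Per-block output resolution / channel / parameter table."""
        c = self.cfg.width()
        ap, ep = self.cfg.attention_pool, self.cfg.encoder_pool
        s = input_size
        rows = []

        def row(name, size, ch, module):
            rows.append(
                {
                    "block": name,
                    "out_size": size,
                    "out_channels": ch,
                    "params": sum(p.data.size for p in module.parameters()),
                }
            )

        row("FP1", s, c, self.enc1)
        row("FSA1", s // ap, 2 * c, self.att1)
        row("FP2", s // (ap * ep), 2 * c, self.enc2)
        row("FP3", s // (ap * ep), 4 * c, self.enc3)
        row("FSA2", s // (ap * ep * ap), 8 * c, self.att2)
        row("FP4", s // (ap * ep * ap * ep), 8 * c, self.enc4)
        row("FP5", s // (ap * ep * ap * ep), 16 * c, self.bottleneck)
        size = s // (ap * ep * ap * ep)
        for i, (block, w) in enumerate(zip(self.dec, self.cfg.decoder_widths)):
            size *= block.up_factor
            row(f"D{i + 1}", size, w, block)
        row("head", s, self.cfg.out_channels, self.head)
        return rows

    def summary_text(self, input_size: int = 512) -> str:
        rows = self.summary(input_size)
        lines = [f"{'block':<6} {'out HxW':>10} {'channels':>9} {'params':>10}"]
        for r in rows:
            lines.append(
                f"{r['block']:<6} {r['out_size']:>4}x{r['out_size']:<5} "
                f"{r['out_channels']:>9} {r['params']:>10}"
            )
        lines.append(f"total parameters: {self.param_count()}")
        return "\n".join(lines)

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        from dataclasses import asdict

        meta = asdict(self.cfg)
        np.savez(path, __cfg__=np.array([repr(meta)]), **self.state_dict())

    @classmethod
    def load(cls, path) -> "AttentionUNet":
        import ast

        with np.load(path, allow_pickle=False) as data:
            meta = ast.literal_eval(str(data["__cfg__"][0]))
            model = cls(NetworkCfg(**meta))
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__cfg__"}
            )
        return model
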