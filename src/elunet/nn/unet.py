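"""Three-level volumetric UNet with explicit backward pass.

Encoder: two double-convolution blocks with max-pool downsampling;
bottleneck double convolution; decoder: trilinear upsampling + halving
convolution, skip concatenation, double convolution; final 1x1x1
projection.  The first ``param_channels`` output channels pass through
softplus so material-parameter heads stay strictly positive; remaining
(stress) heads are linear.

Default widths follow the reference configuration (64, 128, 256); the
reduced presets (e.g. 16/32/64) are first-class for CPU-scale problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv3d, MaxPool3d, Param, ReLU, Softplus, TrilinearUp3d

__all__ = ["UNetConfig", "UNet3D"]


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int
    out_channels: int
    widths: tuple[int, int, int] = (64, 128, 256)
    kernel_size: int = 3
    param_channels: int = 0      # leading output channels forced positive
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if len(self.widths) != 3 or min(self.widths) < 1:
            raise ValueError("widths must be three positive level widths")
        if not 0 <= self.param_channels <= self.out_channels:
            raise ValueError("param_channels out of range")


class _DoubleConv:
    def __init__(self, in_ch, out_ch, rng, dtype):
        self.c1 = Conv3d(in_ch, out_ch, 3, rng, dtype)
        self.r1 = ReLU()
        self.c2 = Conv3d(out_ch, out_ch, 3, rng, dtype)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


class UNet3D:
    """Volumetric encoder-decoder operator (see module docstring)."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        w1, w2, w3 = cfg.widths
        self.enc1 = _DoubleConv(cfg.in_channels, w1, rng, dtype)
        self.pool1 = MaxPool3d()
        self.enc2 = _DoubleConv(w1, w2, rng, dtype)
        self.pool2 = MaxPool3d()
        self.bott = _DoubleConv(w2, w3, rng, dtype)
        self.up2 = TrilinearUp3d(dtype)
        self.upc2 = Conv3d(w3, w2, 3, rng, dtype)
        self.dec2 = _DoubleConv(2 * w2, w2, rng, dtype)
        self.up1 = TrilinearUp3d(dtype)
        self.upc1 = Conv3d(w2, w1, 3, rng, dtype)
        self.dec1 = _DoubleConv(2 * w1, w1, rng, dtype)
        self.head = Conv3d(w1, cfg.out_channels, 1, rng, dtype)
        self.softplus = Softplus()
        self._dtype = dtype

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        blocks = [self.enc1, self.enc2, self.bott, self.upc2, self.dec2,
                  self.upc1, self.dec1, self.head]
        out: list[Param] = []
        for b in blocks:
            out.extend(b.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[0]}"
            )
        if any(n % 4 for n in x.shape[1:]):
            raise ValueError(
                f"grid {x.shape[1:]} must be divisible by 4 (two poolings)"
            )
        x = np.ascontiguousarray(x, dtype=self._dtype)
        e1 = self.enc1.forward(x)
        e2 = self.enc2.forward(self.pool1.forward(e1))
        b = self.bott.forward(self.pool2.forward(e2))
        u2 = self.upc2.forward(self.up2.forward(b))
        d2 = self.dec2.forward(np.concatenate([u2, e2], axis=0))
        u1 = self.upc1.forward(self.up1.forward(d2))
        d1 = self.dec1.forward(np.concatenate([u1, e1], axis=0))
        y = self.head.forward(d1)
        k = self.cfg.param_channels
        if k:
            y = np.concatenate([self.softplus.forward(y[:k]), y[k:]], axis=0)
        self._w12 = (self.upc2.out_ch, self.upc1.out_ch)
        return y

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for d(loss)/d(output) = dy."""
        dy = np.ascontiguousarray(dy, dtype=self._dtype)
        k = self.cfg.param_channels
        if k:
            dy = np.concatenate([self.softplus.backward(dy[:k]), dy[k:]], axis=0)
        dd1 = self.head.backward(dy)
        dcat1 = self.dec1.backward(dd1)
        w2, w1 = self._w12
        du1, de1_skip = dcat1[:w1], dcat1[w1:]
        dd2 = self.upc1.backward(du1)
        dcat2 = self.dec2.backward(self.up1.backward(dd2))
        du2, de2_skip = dcat2[:w2], dcat2[w2:]
        db = self.upc2.backward(du2)
        de2 = self.pool2.backward(self.bott.backward(self.up2.backward(db)))
        de1 = self.pool1.backward(self.enc2.backward(de2 + de2_skip))
        self.enc1.backward(de1 + de1_skip)

    # -- checkpointing ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def save(self, path) -> None:
        meta = dict(
            in_channels=self.cfg.in_channels, out_channels=self.cfg.out_channels,
            widths=np.array(self.cfg.widths), kernel_size=self.cfg.kernel_size,
            param_channels=self.cfg.param_channels, seed=self.cfg.seed,
            dtype=self.cfg.dtype,
        )
        np.savez(path, **self.state_arrays(), __meta__=np.array([repr(meta)]))

    def load_state(self, path) -> None:
        data = np.load(path, allow_pickle=False)
        for i, p in enumerate(self.params()):
            arr = data[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError("checkpoint shape mismatch")
            p.value[...] = arr
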