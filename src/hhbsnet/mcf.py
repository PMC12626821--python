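"""Multi-scale Cavity Fusion (MCF).

An ASPP-style block that widens the receptive field without losing
resolution, then recalibrates the merged features:

* five parallel branches — a 1x1 conv; three depthwise-separable 3x3
  convs dilated at rates 6, 12 and 18 ("same" padding equal to the
  rate); and a global-average-pool branch (1x1 conv on the pooled
  vector, broadcast back over space);
* channel concatenation of the five C-channel outputs and a 1x1
  projection from 5C back to C;
* channel calibration (squeeze-excite style: pool, C -> C/4 -> C MLP,
  sigmoid gate) and spatial calibration (channel mean+max maps, 1x1
  conv to a single gate) applied to the projected map;
* residual fusion: the two calibrated maps and the projected map are
  summed and passed through a final 1x1 conv.

All stages preserve [C, H, W].  The residual term is toggleable via
``residual`` (kept on by default).
"""

from __future__ import annotations

from . import nn
from .autodiff import Tensor, as_tensor, concat

__all__ = ["MCF", "DILATION_RATES"]

DILATION_RATES = (6, 12, 18)


def _with_batch(x) -> tuple[Tensor, bool]:
    t = as_tensor(x)
    if t.ndim == 3:
        return t.reshape(1, *t.shape), True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"expected [C,H,W] or [N,C,H,W], got shape {t.shape}")


def _maybe_squeeze(t: Tensor, squeeze: bool) -> Tensor:
    return t.reshape(t.shape[1:]) if squeeze else t


class _DilatedBranch(nn.Module):
    """Depthwise 3x3 dilated conv + pointwise 1x1, then BN + ReLU."""

    def __init__(self, channels: int, rate: int, padding_mode: str = "zeros"):
        super().__init__()
        self.rate = rate
        self.depthwise = nn.Conv2d(channels, channels, 3, padding=rate,
                                   dilation=rate, groups=channels,
                                   padding_mode=padding_mode)
        self.pointwise = nn.Conv2d(channels, channels, 1)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.pointwise(self.depthwise(x))).relu()


class MCF(nn.Module):
    def __init__(self, channels: int, reduction: int = 4,
                 residual: bool = True, padding_mode: str = "zeros"):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels={channels} must be divisible by the calibration "
                f"bottleneck reduction {reduction}")
        self.channels = channels
        self.residual = residual
        self.branch1_conv = nn.Conv2d(channels, channels, 1)
        self.branch1_bn = nn.BatchNorm2d(channels)
        self.branch2 = _DilatedBranch(channels, DILATION_RATES[0], padding_mode)
        self.branch3 = _DilatedBranch(channels, DILATION_RATES[1], padding_mode)
        self.branch4 = _DilatedBranch(channels, DILATION_RATES[2], padding_mode)
        # pooled 1x1 maps have degenerate batch statistics, so no BN here
        self.branch5_conv = nn.Conv2d(channels, channels, 1)
        self.proj_in = nn.Conv2d(5 * channels, channels, 1)
        self.ca_fc1 = nn.Linear(channels, channels // reduction)
        self.ca_fc2 = nn.Linear(channels // reduction, channels)
        self.sa_conv = nn.Conv2d(2, 1, 1)
        self.proj_out = nn.Conv2d(channels, channels, 1)

    # -- stages --------------------------------------------------------

    def branches(self, x) -> list[Tensor]:
        """The five parallel branch outputs, each [.., C, H, W]."""
        t, squeeze = _with_batch(x)
        n, c, h, w = t.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        b1 = self.branch1_bn(self.branch1_conv(t)).relu()
        b2 = self.branch2(t)
        b3 = self.branch3(t)
        b4 = self.branch4(t)
        pooled = t.mean(axis=(2, 3), keepdims=True)
        b5 = self.branch5_conv(pooled).relu().broadcast_to((n, c, h, w))
        return [_maybe_squeeze(b, squeeze) for b in (b1, b2, b3, b4, b5)]

    def concat_project(self, branch_outputs) -> Tensor:
        """Concatenate five [C, H, W] maps to [5C, H, W]; project to C."""
        tensors = []
        squeeze = False
        for b in branch_outputs:
            t, squeeze = _with_batch(b)
            tensors.append(t)
        shapes = {t.shape for t in tensors}
        if len(tensors) != 5 or len(shapes) != 1:
            raise ValueError(f"expected five equally shaped maps, got {shapes}")
        return _maybe_squeeze(self.proj_in(concat(tensors, axis=1)), squeeze)

    def channel_calibration(self, f) -> Tensor:
        t, squeeze = _with_batch(f)
        n, c, h, w = t.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        pooled = t.mean(axis=(2, 3))                      # [N, C]
        gate = self.ca_fc2(self.ca_fc1(pooled).relu()).sigmoid()
        return _maybe_squeeze(gate.reshape(n, c, 1, 1) * t, squeeze)

    def spatial_calibration(self, f) -> Tensor:
        t, squeeze = _with_batch(f)
        mean_map = t.mean(axis=1, keepdims=True)
        max_map = t.amax(axis=1, keepdims=True)
        gate = self.sa_conv(concat([mean_map, max_map], axis=1)).sigmoid()
        return _maybe_squeeze(gate * t, squeeze)

    def fuse(self, fc, fs, original) -> Tensor:
        tc, squeeze = _with_batch(fc)
        ts, _ = _with_batch(fs)
        to, _ = _with_batch(original)
        if not (tc.shape == ts.shape == to.shape):
            raise ValueError(
                f"fuse expects equal shapes, got {tc.shape}, {ts.shape}, {to.shape}")
        fused = tc + ts
        if self.residual:
            fused = fused + to
        return _maybe_squeeze(self.proj_out(fused), squeeze)

    def forward(self, x) -> Tensor:
        t, squeeze = _with_batch(x)
        merged = self.concat_project(self.branches(t))
        fc = self.channel_calibration(merged)
        fs = self.spatial_calibration(merged)
        return _maybe_squeeze(self.fuse(fc, fs, merged), squeeze)
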