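"""Global Channel–Spatial Attention (GCSA).

The block refines a feature map in three stages:

1. **Channel attention** — the channel axis is moved last and passed
   through a two-layer perceptron (bottleneck C -> C/4 -> C, ReLU in
   between) *independently at every spatial position*; a sigmoid turns
   the result into a gate that multiplies the input.  No spatial pooling
   is involved: the gate is a full C x H x W map.
2. **Channel shuffle** — the channels are split into 4 groups and
   interleaved by the reshape–transpose–flatten permutation, so
   information mixes across groups.
3. **Spatial attention** — a 7x7 convolution bottleneck
   (C -> C/4, BN, ReLU, 7x7 back to C, BN, sigmoid) produces a gate that
   multiplies the shuffled map.

All stages preserve the [C, H, W] shape; both gates are bounded in
(0, 1).  Inputs may be given with or without a leading batch axis.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor

__all__ = [
    "ChannelAttention",
    "SpatialAttention",
    "GCSA",
    "channel_shuffle",
    "shuffle_permutation",
]


def _with_batch(x) -> tuple[Tensor, bool]:
    t = as_tensor(x)
    if t.ndim == 3:
        return t.reshape(1, *t.shape), True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"expected [C,H,W] or [N,C,H,W], got shape {t.shape}")


def _maybe_squeeze(t: Tensor, squeeze: bool) -> Tensor:
    return t.reshape(t.shape[1:]) if squeeze else t


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The channel order produced by the reshape–transpose–flatten shuffle."""
    if channels % groups:
        raise ValueError(f"groups={groups} must divide channels={channels}")
    return (np.arange(channels).reshape(groups, channels // groups)
            .T.reshape(-1))


def channel_shuffle(x, groups: int = 4) -> Tensor:
    """Interleave channels across ``groups``; spatial content untouched."""
    t, squeeze = _with_batch(x)
    n, c, h, w = t.shape
    if c % groups:
        raise ValueError(f"groups={groups} must divide channels={c}")
    out = (t.reshape(n, groups, c // groups, h, w)
           .transpose((0, 2, 1, 3, 4))
           .reshape(n, c, h, w))
    return _maybe_squeeze(out, squeeze)


class ChannelAttention(nn.Module):
    """Per-position channel gate: sigmoid(MLP(x_channel_vector)) * x."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels={channels} must be divisible by the bottleneck "
                f"reduction {reduction}")
        self.channels = channels
        self.mlp1 = nn.Linear(channels, channels // reduction)
        self.mlp2 = nn.Linear(channels // reduction, channels)

    def forward(self, x) -> Tensor:
        t, squeeze = _with_batch(x)
        n, c, h, w = t.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        # move C last, apply the MLP at every position, move back
        flat = t.transpose((0, 2, 3, 1)).reshape(n * h * w, c)
        gate = self.mlp2(self.mlp1(flat).relu()).sigmoid()
        gate = gate.reshape(n, h, w, c).transpose((0, 3, 1, 2))
        return _maybe_squeeze(gate * t, squeeze)


class SpatialAttention(nn.Module):
    """7x7 convolutional gate with a C/4 bottleneck and batch norm."""

    def __init__(self, channels: int, reduction: int = 4, kernel_size: int = 7):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels={channels} must be divisible by the bottleneck "
                f"reduction {reduction}")
        self.channels = channels
        pad = kernel_size // 2
        self.conv1 = nn.Conv2d(channels, channels // reduction, kernel_size, padding=pad)
        self.bn1 = nn.BatchNorm2d(channels // reduction)
        self.conv2 = nn.Conv2d(channels // reduction, channels, kernel_size, padding=pad)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x) -> Tensor:
        t, squeeze = _with_batch(x)
        if t.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {t.shape[1]}")
        gate = self.bn2(self.conv2(self.bn1(self.conv1(t)).relu())).sigmoid()
        return _maybe_squeeze(gate * t, squeeze)


class GCSA(nn.Module):
    """Channel attention -> 4-group channel shuffle -> spatial attention."""

    def __init__(self, channels: int, groups: int = 4):
        super().__init__()
        if channels % groups:
            raise ValueError(f"groups={groups} must divide channels={channels}")
        self.groups = groups
        self.channel_attention = ChannelAttention(channels)
        self.spatial_attention = SpatialAttention(channels)

    def forward(self, x) -> Tensor:
        t, squeeze = _with_batch(x)
        t = self.channel_attention(t)
        t = channel_shuffle(t, self.groups)
        t = self.spatial_attention(t)
        return _maybe_squeeze(t, squeeze)
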