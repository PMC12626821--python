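"""Backbone feature extractors.

A backbone turns an RGB image into four feature maps at strictly
increasing strides.  Two implementations are provided:

* :class:`InvertedResidualBackbone` — a compact MobileNet-style encoder
  (inverted residual bottlenecks with depthwise convolutions) at strides
  (4, 8, 16, 32), intended for real training runs; weights may be loaded
  from a local ``.npz`` file but are never downloaded.
* :class:`TinyBackbone` — a minimal stack of stride-2 conv/BN/ReLU
  stages with configurable strides and widths, small enough that unit
  tests and desk-scale experiments can train it from random init.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor

__all__ = ["TinyBackbone", "InvertedResidualBackbone"]


class _Backbone(nn.Module):
    """Shared contract: four levels at declared strides and widths."""

    feature_strides: tuple[int, int, int, int]
    feature_widths: tuple[int, int, int, int]

    def _check_input(self, x: Tensor) -> Tensor:
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected an RGB image [3,H,W] or [N,3,H,W], got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        s = self.feature_strides[-1]
        if h % s or w % s:
            raise ValueError(
                f"input size {h}x{w} must be divisible by the largest stride {s}")
        return x


def _stage(cin: int, cout: int, ratio: int) -> nn.Sequential:
    """Downsample by ``ratio`` (a power of two) with stride-2 conv blocks."""
    if ratio < 1 or ratio & (ratio - 1):
        raise ValueError(f"stride ratio must be a power of two, got {ratio}")
    layers: list[nn.Module] = []
    c = cin
    steps = max(ratio.bit_length() - 1, 0)
    for i in range(steps):
        out_c = cout if i == steps - 1 else max(cout // 2, 4)
        layers += [nn.Conv2d(c, out_c, 3, stride=2, padding=1, bias=False),
                   nn.BatchNorm2d(out_c), nn.ReLU()]
        c = out_c
    if not layers:  # ratio 1: plain 3x3 block
        layers = [nn.Conv2d(c, cout, 3, padding=1, bias=False),
                  nn.BatchNorm2d(cout), nn.ReLU()]
    return nn.Sequential(*layers)


class TinyBackbone(_Backbone):
    """Four stride-2 stages; defaults keep 64x64 test scenes at a 32x32 trunk."""

    def __init__(self,
                 feature_strides: tuple[int, int, int, int] = (2, 4, 8, 16),
                 feature_widths: tuple[int, int, int, int] = (8, 16, 24, 32)):
        super().__init__()
        if len(feature_strides) != 4 or len(feature_widths) != 4:
            raise ValueError("a backbone declares exactly four levels")
        if any(b <= a for a, b in zip(feature_strides, feature_strides[1:])):
            raise ValueError("feature strides must be strictly increasing")
        self.feature_strides = tuple(feature_strides)
        self.feature_widths = tuple(feature_widths)
        widths = (3,) + self.feature_widths
        strides = (1,) + self.feature_strides
        for i in range(4):
            setattr(self, f"stage{i + 1}",
                    _stage(widths[i], widths[i + 1], strides[i + 1] // strides[i]))

    def forward(self, x) -> list[Tensor]:
        x = self._check_input(as_tensor(x))
        feats = []
        for i in range(4):
            x = getattr(self, f"stage{i + 1}")(x)
            feats.append(x)
        return feats


class _InvertedResidual(nn.Module):
    """Expand (1x1) -> depthwise 3x3 -> project (1x1), skip when shapes allow."""

    def __init__(self, cin: int, cout: int, stride: int, expansion: int = 4):
        super().__init__()
        mid = cin * expansion
        self.use_skip = stride == 1 and cin == cout
        self.expand = nn.Conv2d(cin, mid, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(mid)
        self.depthwise = nn.Conv2d(mid, mid, 3, stride=stride, padding=1,
                                   groups=mid, bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        self.project = nn.Conv2d(mid, cout, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.expand(x)).relu()
        out = self.bn2(self.depthwise(out)).relu()
        out = self.bn3(self.project(out))
        if self.use_skip:
            out = out + x
        return out


class InvertedResidualBackbone(_Backbone):
    """MobileNet-style encoder at strides (4, 8, 16, 32)."""

    feature_strides = (4, 8, 16, 32)
    feature_widths = (16, 24, 32, 64)

    def __init__(self, weights_file: str | None = None):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Conv2d(3, 8, 3, stride=2, padding=1, bias=False),
            nn.BatchNorm2d(8), nn.ReLU())
        self.stage1 = nn.Sequential(
            _InvertedResidual(8, 16, stride=2),
            _InvertedResidual(16, 16, stride=1))
        self.stage2 = nn.Sequential(
            _InvertedResidual(16, 24, stride=2),
            _InvertedResidual(24, 24, stride=1))
        self.stage3 = nn.Sequential(
            _InvertedResidual(24, 32, stride=2),
            _InvertedResidual(32, 32, stride=1))
        self.stage4 = nn.Sequential(
            _InvertedResidual(32, 64, stride=2),
            _InvertedResidual(64, 64, stride=1))
        if weights_file is not None:
            with np.load(weights_file) as state:
                self.load_state_dict({k: state[k] for k in state.files})

    def forward(self, x) -> list[Tensor]:
        x = self._check_input(as_tensor(x))
        x = self.stem(x)
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        return [f1, f2, f3, f4]
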