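"""HHBSNet: the assembled segmentation network.

Pipeline (single trunk, shape-preserving blocks):

    backbone (4 levels) -> infusion(first, last) -> GCSA -> MCF
        -> global feature fusion -> 1x1 classifier -> bilinear upsample
        -> per-pixel softmax

The infusion block upsamples the deepest backbone level to the first
level's resolution, concatenates (shallow, deep) and projects with a
1x1 conv to the trunk width, so shallow texture and deep semantics mix
before the attention blocks.  Global feature fusion injects a pooled
image-level descriptor back into every position.  Class masks derive
from the per-pixel argmax (ties break toward the lower class index).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn
from .attention import GCSA
from .autodiff import Tensor, as_tensor, bilinear_resize, concat, log_softmax
from .backbone import InvertedResidualBackbone, TinyBackbone
from .mcf import MCF

__all__ = ["NetworkConfig", "Infusion", "GlobalFeatureFusion", "HHBSNet",
           "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``working_width`` is the channel count of the post-infusion trunk
    (divisible by 4 for the attention bottlenecks); ``backbone`` selects
    ``"inverted_residual"`` (stride-4..32 encoder) or ``"tiny"`` (the
    small test-scale encoder).
    """

    num_classes: int = 6
    input_size: int = 512
    working_width: int = 256
    backbone: str = "inverted_residual"
    use_pretrained_backbone: bool = False
    backbone_weights: str | None = None
    mcf_residual: bool = True

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if self.working_width % 4:
            raise ValueError("working_width must be divisible by 4")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class Infusion(nn.Module):
    """Fuse the shallowest and deepest backbone levels.

    The deep map is bilinearly upsampled to the shallow map's spatial
    size, concatenated (shallow first), and projected by a 1x1 conv to
    the trunk width.
    """

    def __init__(self, shallow_channels: int, deep_channels: int, out_channels: int):
        super().__init__()
        self.project = nn.Conv2d(shallow_channels + deep_channels, out_channels, 1)

    def forward(self, shallow, deep) -> Tensor:
        s = as_tensor(shallow)
        d = as_tensor(deep)
        squeeze = s.ndim == 3
        if squeeze:
            s = s.reshape(1, *s.shape)
            d = d.reshape(1, *d.shape)
        d = bilinear_resize(d, s.shape[2], s.shape[3])
        out = self.project(concat([s, d], axis=1))
        return out.reshape(out.shape[1:]) if squeeze else out


class GlobalFeatureFusion(nn.Module):
    """Inject a pooled global descriptor back into every position."""

    def __init__(self, channels: int):
        super().__init__()
        self.global_proj = nn.Conv2d(channels, channels, 1)
        self.fuse = nn.Conv2d(2 * channels, channels, 1)

    def forward(self, x) -> Tensor:
        t = as_tensor(x)
        squeeze = t.ndim == 3
        if squeeze:
            t = t.reshape(1, *t.shape)
        n, c, h, w = t.shape
        pooled = t.mean(axis=(2, 3), keepdims=True)
        g = self.global_proj(pooled).broadcast_to((n, c, h, w))
        out = self.fuse(concat([t, g], axis=1))
        return out.reshape(out.shape[1:]) if squeeze else out


def _make_backbone(cfg: NetworkConfig):
    if cfg.backbone == "tiny":
        return TinyBackbone()
    if cfg.backbone == "inverted_residual":
        weights = cfg.backbone_weights if cfg.use_pretrained_backbone else None
        return InvertedResidualBackbone(weights_file=weights)
    raise ValueError(f"unknown backbone {cfg.backbone!r}")


class HHBSNet(nn.Module):
    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        self.config = config or NetworkConfig()
        self.backbone = _make_backbone(self.config)
        widths = self.backbone.feature_widths
        w = self.config.working_width
        self.infusion = Infusion(widths[0], widths[-1], w)
        self.gcsa = GCSA(w)
        self.mcf = MCF(w, residual=self.config.mcf_residual)
        self.global_fusion = GlobalFeatureFusion(w)
        self.classifier = nn.Conv2d(w, self.config.num_classes, 1)

    def forward(self, image) -> Tensor:
        """Per-pixel class logits at input resolution, [.., K, H, W]."""
        t = as_tensor(image)
        squeeze = t.ndim == 3
        if squeeze:
            t = t.reshape(1, *t.shape)
        h, w = t.shape[2], t.shape[3]
        feats = self.backbone(t)
        trunk = self.infusion(feats[0], feats[-1])
        trunk = self.gcsa(trunk)
        trunk = self.mcf(trunk)
        trunk = self.global_fusion(trunk)
        logits = self.classifier(trunk)
        logits = bilinear_resize(logits, h, w)
        return logits.reshape(logits.shape[1:]) if squeeze else logits

    def predict_proba(self, image) -> np.ndarray:
        """Inference-mode per-pixel class probabilities (numpy)."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(image)
        finally:
            self.train(was_training)
        axis = 0 if logits.ndim == 3 else 1
        return np.exp(log_softmax(logits, axis=axis).data)

    def predict_mask(self, image) -> np.ndarray:
        """Argmax class mask; ties break toward the lower class index."""
        probs = self.predict_proba(image)
        axis = 0 if probs.ndim == 3 else 1
        return probs.argmax(axis=axis).astype(np.int64)


def save_checkpoint(path, model: HHBSNet) -> None:
    """Persist parameters plus the architecture config in one .npz file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> HHBSNet:
    with np.load(path) as data:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        model = HHBSNet(cfg)
        model.load_state_dict(
            {k: data[k] for k in data.files if k != "__config__"})
    return model
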