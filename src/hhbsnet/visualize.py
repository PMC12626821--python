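"""Prediction visualization: boundary overlays and probability heatmaps."""

from __future__ import annotations

import math

import numpy as np

from .data import DEFAULT_SCHEMA, LabelSchema
from .network import HHBSNet

__all__ = ["boundary_4connected", "predict_overlay", "render_heatmap_grid"]


def boundary_4connected(mask: np.ndarray) -> np.ndarray:
    """Inner boundary of a boolean mask under 4-connectivity.

    A pixel is boundary when it is set but at least one of its 4
    neighbours (treating out-of-image as unset) is not — the morphological
    gradient mask & ~erosion(mask).
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    eroded = (padded[1:-1, 1:-1] & padded[:-2, 1:-1] & padded[2:, 1:-1]
              & padded[1:-1, :-2] & padded[1:-1, 2:])
    return m & ~eroded


def _pad_to_multiple(image: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple]:
    h, w = image.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image, (0, 0)
    padded = np.pad(image, ((0, 0), (0, ph), (0, pw)), mode="edge")
    return padded, (ph, pw)


def predict_overlay(model: HHBSNet, image: np.ndarray,
                    schema: LabelSchema = DEFAULT_SCHEMA,
                    verbose: bool = False):
    """Segment an image and render the study-style overlay.

    Returns ``(mask, overlay, probs)``: the argmax mask, an RGB overlay
    with HHB lesion boundaries in red and the face contour in green,
    and the per-class probability map.  Images whose size is not
    divisible by the backbone stride are padded and un-padded
    automatically (with a notice when ``verbose``).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError(f"expected an RGB image [3, H, W], got {image.shape}")
    stride = model.backbone.feature_strides[-1]
    h, w = image.shape[1:]
    padded, (ph, pw) = _pad_to_multiple(image, stride)
    if (ph or pw) and verbose:
        print(f"notice: padded {h}x{w} input by ({ph}, {pw}) to a multiple "
              f"of stride {stride}")
    probs = model.predict_proba(padded)[:, :h, :w]
    mask = probs.argmax(axis=0)

    overlay = np.clip(image.copy(), 0.0, 1.0)
    hhb = schema.index("HHB")
    face_contour = boundary_4connected(mask != 0)
    lesion_contour = boundary_4connected(mask == hhb)
    overlay[:, face_contour] = np.array([0.0, 1.0, 0.0])[:, None]
    overlay[:, lesion_contour] = np.array([1.0, 0.0, 0.0])[:, None]
    return mask, overlay, probs


def render_heatmap_grid(probs: np.ndarray,
                        schema: LabelSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Tile per-class probability heatmaps into one RGB image array."""
    from matplotlib import colormaps

    k, h, w = probs.shape
    cols = math.ceil(math.sqrt(k))
    rows = math.ceil(k / cols)
    grid = np.zeros((rows * h, cols * w, 3))
    colormap = colormaps["inferno"]
    for c in range(k):
        r, col = divmod(c, cols)
        tile = colormap(np.clip(probs[c], 0.0, 1.0))[..., :3]
        grid[r * h:(r + 1) * h, col * w:(col + 1) * w] = tile
    return grid
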