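"""Synthetic facial-lesion scene generator.

Real clinical melasma photographs are private, so tests and desk-scale
experiments run on generated scenes that emulate their documented
difficulties: lesions with low contrast against surrounding skin,
irregular blurred boundaries, illumination gradients across the face,
and specular highlights.

A scene is an elliptical "face" on a dark background, partitioned into
the facial label regions — ET (forehead band), LF/RF (left/right
mid-face), XB (chin band) — with HHB melasma lesions placed inside the
face as thresholded smoothed-noise blobs.  The mask records the exact
(un-blurred) lesion support; boundary blur, lighting and highlights
perturb the image only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import DEFAULT_SCHEMA, LabelSchema

__all__ = ["SceneSpec", "SceneGenerationError", "synth_face_scene",
           "generate_dataset"]


class SceneGenerationError(RuntimeError):
    """Raised when lesion placement fails after bounded retries."""


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``lesion_contrast`` is the mean intensity offset of lesion pixels
    relative to the surrounding skin (kept small to emulate the low
    lesion/skin contrast of melasma); ``boundary_blur`` is the Gaussian
    sigma (pixels) applied to the lesion alpha so image boundaries are
    soft while the mask stays crisp; ``illumination_gradient`` is the
    maximum relative brightness slope across the scene.
    """

    image_size: int = 512
    lesion_count: tuple[int, int] = (2, 6)
    lesion_contrast: float = 0.12
    boundary_blur: float = 1.5
    illumination_gradient: float = 0.25
    specular_spots: int = 3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        lo, hi = self.lesion_count
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid lesion_count range {self.lesion_count}")
        if not 0.0 <= self.lesion_contrast < 0.5:
            raise ValueError("lesion_contrast must stay within valid intensity range")


def _face_geometry(size: int, rng: np.random.Generator):
    cy = cx = size / 2.0
    ax = 0.32 * size * rng.uniform(0.92, 1.08)
    by = 0.42 * size * rng.uniform(0.92, 1.08)
    return cy, cx, ax, by


def _ellipse_mask(size: int, cy: float, cx: float, ax: float, by: float,
                  shrink: float = 1.0) -> np.ndarray:
    ys, xs = np.mgrid[0:size, 0:size]
    return (((xs - cx) / (ax * shrink)) ** 2
            + ((ys - cy) / (by * shrink)) ** 2) <= 1.0


def _region_mask(size: int, rng: np.random.Generator,
                 schema: LabelSchema) -> tuple[np.ndarray, np.ndarray, tuple]:
    geom = _face_geometry(size, rng)
    cy, cx, ax, by = geom
    face = _ellipse_mask(size, *geom)
    ys, xs = np.mgrid[0:size, 0:size]
    v = (ys - (cy - by)) / (2.0 * by)  # 0 at the top of the face, 1 at the chin
    forehead_cut = rng.uniform(0.30, 0.38)
    chin_cut = rng.uniform(0.74, 0.82)
    midline = cx + rng.uniform(-0.02, 0.02) * size
    mask = np.zeros((size, size), dtype=np.uint8)
    et, hhb, xb, lf, rf = (schema.index(n) for n in ("ET", "HHB", "XB", "LF", "RF"))
    mask[face & (v < forehead_cut)] = et
    mask[face & (v >= forehead_cut) & (v <= chin_cut) & (xs < midline)] = lf
    mask[face & (v >= forehead_cut) & (v <= chin_cut) & (xs >= midline)] = rf
    mask[face & (v > chin_cut)] = xb
    return mask, face, geom


def _lesion_blob(size: int, center: tuple[int, int], radius: float,
                 allowed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Irregular blob: thresholded smoothed noise inside a soft disc."""
    cy, cx = center
    ys, xs = np.mgrid[0:size, 0:size]
    dist2 = ((ys - cy) ** 2 + (xs - cx) ** 2) / radius**2
    envelope = np.exp(-dist2)
    field = gaussian_filter(rng.standard_normal((size, size)),
                            sigma=max(radius / 2.5, 1.0))
    spread = field.std()
    if spread > 0:
        field = field / spread
    bumpy = envelope * (1.0 + 0.45 * field)
    return (bumpy > np.exp(-1.0)) & allowed


def synth_face_scene(spec: SceneSpec,
                     schema: LabelSchema = DEFAULT_SCHEMA
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image [3,H,W] float32 in [0,1], mask [H,W] uint8) pair.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    mask, face, geom = _region_mask(size, rng, schema)
    hhb = schema.index("HHB")

    # base colours: warm skin inside the face, dark backdrop outside
    skin = np.array([0.82, 0.66, 0.55]) + rng.uniform(-0.04, 0.04, size=3)
    backdrop = np.array([0.18, 0.19, 0.23]) + rng.uniform(-0.02, 0.02, size=3)
    image = np.where(face[None], skin[:, None, None], backdrop[:, None, None])

    # lesions: strictly inside the face (eroded ellipse), recorded crisp
    interior = _ellipse_mask(size, *geom, shrink=0.9)
    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    lesion_support = np.zeros((size, size), dtype=bool)
    candidates = np.flatnonzero(interior)
    for _ in range(n_lesions):
        for attempt in range(20):
            flat = int(rng.choice(candidates))
            center = (flat // size, flat % size)
            radius = rng.uniform(0.05, 0.12) * size
            blob = _lesion_blob(size, center, radius, interior, rng)
            if blob.sum() >= 16:
                lesion_support |= blob
                break
        else:
            raise SceneGenerationError(
                f"could not place a lesion of at least 16 px after 20 tries "
                f"for spec {spec}")
    mask[lesion_support] = hhb

    # image-side lesion appearance: soft-edged brownish darkening
    alpha = gaussian_filter(lesion_support.astype(np.float64),
                            sigma=spec.boundary_blur)
    tint = np.array([0.85, 1.0, 0.75])  # melasma darkens green/red more than blue
    image = image - spec.lesion_contrast * tint[:, None, None] * alpha[None]

    # illumination gradient (image only)
    if spec.illumination_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        ys, xs = np.mgrid[0:size, 0:size]
        proj = ((np.cos(theta) * (xs - size / 2)
                 + np.sin(theta) * (ys - size / 2)) / size)
        image = image * (1.0 + spec.illumination_gradient * proj)[None]

    # specular highlights (image only)
    for _ in range(spec.specular_spots):
        flat = int(rng.choice(candidates))
        sy, sx = flat // size, flat % size
        sigma = rng.uniform(0.01, 0.03) * size
        ys, xs = np.mgrid[0:size, 0:size]
        bump = np.exp(-((ys - sy) ** 2 + (xs - sx) ** 2) / (2 * sigma**2))
        image = image + 0.25 * bump[None]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    return np.clip(image, 0.0, 1.0).astype(np.float32), mask


def generate_dataset(n: int, base_spec: SceneSpec | None = None,
                     seed: int = 0,
                     schema: LabelSchema = DEFAULT_SCHEMA) -> list[dict]:
    """Generate ``n`` scenes with per-scene seeds derived from ``seed``."""
    base = base_spec or SceneSpec()
    records = []
    for i in range(n):
        spec = dataclasses.replace(base, seed=(seed * 100003 + i) % (2**31 - 1))
        image, mask = synth_face_scene(spec, schema)
        records.append({"basename": f"scene_{i:04d}", "image": image,
                        "mask": mask, "spec": spec})
    return records
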