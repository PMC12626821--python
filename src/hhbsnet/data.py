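"""Dataset plumbing: label schema, polygon rasterization, the 8:1:1
split, on-the-fly augmentation, and image/mask I/O.

Masks are single-channel 8-bit indexed PNGs whose pixel values are the
schema indices; LabelMe-style polygon JSON (``shapes[].label``,
``shapes[].points``) is accepted as an alternative annotation format and
rasterized on load.  Raster convention: 0-based indices, origin top
left, pixel-centre sampling.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

__all__ = [
    "LabelSchema",
    "DEFAULT_SCHEMA",
    "SplitAssignment",
    "rasterize_polygons",
    "split_dataset",
    "augment",
    "synth_to_image",
    "save_pair",
    "load_dataset",
    "load_labelme",
    "write_manifest",
    "read_manifest",
]


@dataclasses.dataclass(frozen=True)
class LabelSchema:
    """Ordered class names; index = mask value.

    Default facial schema: BACKGROUND, ET (forehead), HHB (melasma
    lesion), XB (chin), LF / RF (left / right facial areas).
    """

    names: tuple[str, ...] = ("BACKGROUND", "ET", "HHB", "XB", "LF", "RF")

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValueError(f"unknown class name {name!r}; schema is {self.names}")


DEFAULT_SCHEMA = LabelSchema()


@dataclasses.dataclass
class SplitAssignment:
    train: list[int]
    val: list[int]
    test: list[int]
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.val), len(self.test))


def rasterize_polygons(polygons, size: int | tuple[int, int],
                       schema: LabelSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Rasterize (class_name, vertices) polygons to an indexed mask.

    Vertices are (x, y) pairs; a pixel belongs to a polygon when its
    centre lies inside.  Later polygons overwrite earlier ones; pixels
    outside every polygon are BACKGROUND (0).
    """
    if isinstance(size, int):
        h = w = size
    else:
        h, w = size
    mask = np.zeros((h, w), dtype=np.uint8)
    if not polygons:
        return mask
    ys, xs = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xs.reshape(-1) + 0.0, ys.reshape(-1) + 0.0])
    for name, vertices in polygons:
        idx = schema.index(name)
        verts = np.asarray(vertices, dtype=np.float64)
        if verts.ndim != 2 or verts.shape[0] < 3:
            raise ValueError(f"polygon for {name!r} needs at least 3 vertices")
        inside = MplPath(verts).contains_points(centers).reshape(h, w)
        mask[inside] = idx
    return mask


def split_dataset(n: int, seed: int) -> SplitAssignment:
    """8:1:1 split by seeded shuffle: val = test = floor(n/10)."""
    if n < 10:
        raise ValueError(f"need at least 10 items for an 8:1:1 split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = n // 10
    n_test = n // 10
    return SplitAssignment(
        train=sorted(int(i) for i in order[: n - n_val - n_test]),
        val=sorted(int(i) for i in order[n - n_val - n_test: n - n_test]),
        test=sorted(int(i) for i in order[n - n_test:]),
        seed=seed,
    )


def _resize(image: np.ndarray, size: tuple[int, int], nearest: bool) -> np.ndarray:
    """Resize HxW or HxWx3 float arrays via PIL."""
    h, w = size
    resample = Image.NEAREST if nearest else Image.BILINEAR
    if image.ndim == 2:
        return np.asarray(
            Image.fromarray(image).resize((w, h), resample=resample))
    planes = [np.asarray(Image.fromarray(image[..., c]).resize(
        (w, h), resample=resample)) for c in range(image.shape[-1])]
    return np.stack(planes, axis=-1)


def augment(image: np.ndarray, mask: np.ndarray, seed: int | np.random.Generator,
            crop_scale_range: tuple[float, float] = (0.7, 1.0),
            flip_prob: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Random horizontal/vertical flips and a random resized crop.

    ``image`` is [3, H, W] float, ``mask`` is [H, W] int; both receive
    the identical geometric transform (bilinear vs nearest resampling).
    """
    rng = seed if hasattr(seed, "random") else np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask)
    if img.shape[1:] != msk.shape:
        raise ValueError(f"image {img.shape} and mask {msk.shape} are misaligned")
    if rng.random() < flip_prob:  # horizontal
        img = img[:, :, ::-1]
        msk = msk[:, ::-1]
    if rng.random() < flip_prob:  # vertical
        img = img[:, ::-1, :]
        msk = msk[::-1, :]
    h, w = msk.shape
    scale = rng.uniform(*crop_scale_range)
    ch, cw = max(1, round(h * scale)), max(1, round(w * scale))
    top = rng.integers(0, h - ch + 1)
    left = rng.integers(0, w - cw + 1)
    img = img[:, top:top + ch, left:left + cw]
    msk = msk[top:top + ch, left:left + cw]
    if (ch, cw) != (h, w):
        img = _resize(np.moveaxis(img, 0, -1), (h, w), nearest=False)
        img = np.moveaxis(img, -1, 0)
        msk = _resize(msk.astype(np.uint8), (h, w), nearest=True).astype(mask.dtype)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def synth_to_image(image: np.ndarray) -> Image.Image:
    """[3, H, W] float in [0, 1] -> PIL RGB image."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    arr = (np.moveaxis(arr, 0, -1) * 255.0).round().astype(np.uint8)
    return Image.fromarray(arr, mode="RGB")


def save_pair(root, basename: str, image: np.ndarray, mask: np.ndarray) -> None:
    """Write ``<basename>.png`` (RGB) and ``<basename>_mask.png`` (indexed)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    synth_to_image(image).save(root / f"{basename}.png")
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(
        root / f"{basename}_mask.png")


def load_labelme(path, schema: LabelSchema = DEFAULT_SCHEMA,
                 size: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize a LabelMe-style polygon JSON file to an indexed mask."""
    with open(path) as fh:
        doc = json.load(fh)
    if size is None:
        size = (doc["imageHeight"], doc["imageWidth"])
    polygons = [(shape["label"], shape["points"]) for shape in doc["shapes"]]
    return rasterize_polygons(polygons, size, schema)


def load_dataset(root, schema: LabelSchema = DEFAULT_SCHEMA) -> list[dict]:
    """Load (image, mask) pairs from a directory, ordered by basename.

    Expects ``X.png``/``X.jpg`` images with either ``X_mask.png``
    indexed masks or ``X.json`` LabelMe annotations.  Returns records
    ``{"basename", "image" [3,H,W] float in [0,1], "mask" [H,W] uint8}``.
    """
    root = Path(root)
    images = sorted(p for p in root.iterdir()
                    if p.suffix.lower() in (".png", ".jpg", ".jpeg")
                    and not p.stem.endswith("_mask"))
    records = []
    errors = []
    for img_path in images:
        mask_path = root / f"{img_path.stem}_mask.png"
        json_path = root / f"{img_path.stem}.json"
        with Image.open(img_path) as im:
            image = np.moveaxis(
                np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0, -1, 0)
        if mask_path.exists():
            with Image.open(mask_path) as mm:
                mask = np.asarray(mm.convert("L"), dtype=np.uint8)
        elif json_path.exists():
            mask = load_labelme(json_path, schema, size=image.shape[1:])
        else:
            errors.append(f"{img_path.name}: no mask or annotation file")
            continue
        if mask.shape != image.shape[1:]:
            errors.append(f"{img_path.name}: mask {mask.shape} does not match "
                          f"image {image.shape[1:]}")
            continue
        if mask.max(initial=0) >= schema.num_classes:
            errors.append(f"{img_path.name}: label {int(mask.max())} outside "
                          f"schema of {schema.num_classes} classes")
            continue
        records.append({"basename": img_path.stem, "image": image, "mask": mask})
    if errors:
        raise ValueError("dataset validation failed:\n  " + "\n  ".join(errors))
    return records


def write_manifest(path, basenames: list[str], splits: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["basename", "split"])
        for b, s in zip(basenames, splits):
            writer.writerow([b, s])


def read_manifest(path) -> dict[str, str]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return {row["basename"]: row["split"] for row in reader}
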