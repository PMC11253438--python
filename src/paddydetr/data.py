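"""Dataset plumbing: annotation records, mosaic tiling, size strata,
augmentation and the train/val/test split.

Conventions: pixel coordinates are 0-based half-open, (x, y) = (column, row),
boxes are (xmin, ymin, xmax, ymax).  The three annotation classes are the
field ridge, the single barnyard-grass plant and the continuous
barnyard-grass patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from PIL import Image

LABELS = ("field_ridge", "single_barnyard_grass", "patch_barnyard_grass")
LABEL_TO_INDEX = {name: i for i, name in enumerate(LABELS)}

# display names as they appear in annotation files
LABEL_ALIASES = {
    "field_ridge": "field_ridge",
    "Field ridge": "field_ridge",
    "single_barnyard_grass": "single_barnyard_grass",
    "Single barnyard grass plant": "single_barnyard_grass",
    "patch_barnyard_grass": "patch_barnyard_grass",
    "Continuous patches of barnyard grass": "patch_barnyard_grass",
}

# tile-border clipping policy: drop a clipped box that keeps less than this
# fraction of its original area or whose clipped side is shorter than this
MIN_CLIP_AREA_FRACTION = 0.25
MIN_CLIP_SIDE = 4.0


class SizeClass(Enum):
    """COCO size strata on box area: small <= 32^2 < medium <= 96^2 < large."""

    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


SMALL_MAX_AREA = 32.0 ** 2
MEDIUM_MAX_AREA = 96.0 ** 2


@dataclass(frozen=True)
class BoxAnnotation:
    label: str
    box: tuple  # (xmin, ymin, xmax, ymax), pixels

    def __post_init__(self):
        if self.label not in LABEL_TO_INDEX:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}: need xmin < xmax and ymin < ymax")

    @property
    def area(self) -> float:
        x1, y1, x2, y2 = self.box
        return (x2 - x1) * (y2 - y1)

    @property
    def label_index(self) -> int:
        return LABEL_TO_INDEX[self.label]


@dataclass
class AnnotatedImage:
    pixels: np.ndarray  # H x W x 3 uint8
    annotations: list = field(default_factory=list)
    source_id: str = ""
    tile_origin: tuple | None = None  # (row, col) offset in the parent mosaic
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 raster")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be non-empty")
        h, w = self.pixels.shape[:2]
        for ann in self.annotations:
            x1, y1, x2, y2 = ann.box
            if not (0 <= x1 and 0 <= y1 and x2 <= w and y2 <= h):
                raise ValueError(f"annotation box {ann.box} outside image {w}x{h}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    ratios: tuple = (7, 2, 1)
    seed: int = 0


def classify_size(ann: BoxAnnotation | float) -> SizeClass:
    """Assign the COCO size stratum of a box (or raw area, in pixels^2)."""
    area = ann.area if isinstance(ann, BoxAnnotation) else float(ann)
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    if area <= SMALL_MAX_AREA:
        return SizeClass.SMALL
    if area <= MEDIUM_MAX_AREA:
        return SizeClass.MEDIUM
    return SizeClass.LARGE


def _clip_annotation(ann: BoxAnnotation, x0: float, y0: float, x1: float, y1: float):
    """Clip a box to the window [x0,x1)x[y0,y1); None if the remnant is degenerate."""
    bx1, by1, bx2, by2 = ann.box
    cx1, cy1 = max(bx1, x0), max(by1, y0)
    cx2, cy2 = min(bx2, x1), min(by2, y1)
    if cx2 - cx1 < MIN_CLIP_SIDE or cy2 - cy1 < MIN_CLIP_SIDE:
        return None
    if (cx2 - cx1) * (cy2 - cy1) < MIN_CLIP_AREA_FRACTION * ann.area:
        return None
    return BoxAnnotation(ann.label, (cx1 - x0, cy1 - y0, cx2 - x0, cy2 - y0))


def tile_image(mosaic: AnnotatedImage, tile: int = 600) -> list[AnnotatedImage]:
    """Cut a mosaic into non-overlapping tile x tile sub-images.

    Border strips narrower than the tile are dropped.  Each annotation is
    reassigned to every tile it intersects, clipped to the tile, and discarded
    when the clipped remnant is a sliver (under 25% of its original area or a
    side shorter than 4 px).
    """
    if tile < 1:
        raise ValueError("tile size must be >= 1")
    h, w = mosaic.height, mosaic.width
    n_rows, n_cols = h // tile, w // tile
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"tile {tile} exceeds mosaic {w}x{h}; no tiles produced", stacklevel=2
        )
        return []
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile, c * tile
            pix = mosaic.pixels[y0 : y0 + tile, x0 : x0 + tile]
            anns = []
            for ann in mosaic.annotations:
                clipped = _clip_annotation(ann, x0, y0, x0 + tile, y0 + tile)
                if clipped is not None:
                    anns.append(clipped)
            tiles.append(
                AnnotatedImage(
                    pixels=pix.copy(),
                    annotations=anns,
                    source_id=f"{mosaic.source_id}_r{r}c{c}",
                    tile_origin=(y0, x0),
                )
            )
    return tiles


def split_dataset(samples: list, ratios: tuple = (7, 2, 1), seed: int = 0) -> DatasetSplit:
    """Disjoint, exhaustive, seed-shuffled split; sizes floor(n*r/sum(r)) with
    the remainder assigned to the training set."""
    if any(r <= 0 for r in ratios) or len(ratios) != 3:
        raise ValueError("ratios must be three positive numbers")
    n = len(samples)
    total = sum(ratios)
    n_val = int(n * ratios[1] // total)
    n_test = int(n * ratios[2] // total)
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train : n_train + n_val]]
    test = [samples[i] for i in order[n_train + n_val :]]
    return DatasetSplit(train=train, val=val, test=test, ratios=tuple(ratios), seed=seed)


def resize_to_model(img: AnnotatedImage, side: int = 640) -> AnnotatedImage:
    """Bilinear resample to side x side x 3; boxes scale by (side/W, side/H)."""
    if img.height == side and img.width == side:
        return img
    sx, sy = side / img.width, side / img.height
    pil = Image.fromarray(np.ascontiguousarray(img.pixels))
    pix = np.asarray(pil.resize((side, side), Image.BILINEAR))
    anns = [
        BoxAnnotation(a.label, (a.box[0] * sx, a.box[1] * sy, a.box[2] * sx, a.box[3] * sy))
        for a in img.annotations
    ]
    return replace(img, pixels=pix, annotations=anns)


# ---------------------------------------------------------------------------
# fourfold augmentation
# ---------------------------------------------------------------------------
def _rotate90(img: AnnotatedImage, k: int) -> AnnotatedImage:
    """Rotate by k*90 degrees counter-clockwise with exact box remapping."""
    h, w = img.height, img.width
    pix = np.rot90(img.pixels, k).copy()
    anns = []
    for a in img.annotations:
        x1, y1, x2, y2 = a.box
        if k % 4 == 1:  # (x, y) -> (y, w - x)
            nb = (y1, w - x2, y2, w - x1)
        elif k % 4 == 2:
            nb = (w - x2, h - y2, w - x1, h - y1)
        elif k % 4 == 3:  # (x, y) -> (h - y, x)
            nb = (h - y2, x1, h - y1, x2)
        else:
            nb = (x1, y1, x2, y2)
        anns.append(BoxAnnotation(a.label, nb))
    return replace(img, pixels=pix, annotations=anns)


def _random_crop(img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    """Crop a random sub-window (60-90% per side) and zero-pad back to size."""
    h, w = img.height, img.width
    fh, fw = rng.uniform(0.6, 0.9, size=2)
    ch, cw = max(int(h * fh), 1), max(int(w * fw), 1)
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    out = np.zeros_like(img.pixels)
    py = int(rng.integers(0, h - ch + 1))
    px = int(rng.integers(0, w - cw + 1))
    out[py : py + ch, px : px + cw] = img.pixels[y0 : y0 + ch, x0 : x0 + cw]
    anns = []
    for a in img.annotations:
        clipped = _clip_annotation(a, x0, y0, x0 + cw, y0 + ch)
        if clipped is not None:
            b = clipped.box
            anns.append(BoxAnnotation(a.label, (b[0] + px, b[1] + py, b[2] + px, b[3] + py)))
    return replace(img, pixels=out, annotations=anns)


def _color_jitter(img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    """HSV jitter: hue shift +-18 deg, saturation/value scale in [0.7, 1.3]."""
    hsv = np.asarray(Image.fromarray(np.ascontiguousarray(img.pixels)).convert("HSV")).astype(
        np.int32
    )
    dh = int(rng.integers(-13, 14))  # 255-scale hue: ~18 degrees
    ss, vs = rng.uniform(0.7, 1.3, size=2)
    hsv[..., 0] = (hsv[..., 0] + dh) % 256
    hsv[..., 1] = np.clip(hsv[..., 1] * ss, 0, 255)
    hsv[..., 2] = np.clip(hsv[..., 2] * vs, 0, 255)
    rgb = Image.fromarray(hsv.astype(np.uint8), mode="HSV").convert("RGB")
    return replace(img, pixels=np.asarray(rgb), annotations=list(img.annotations))


def _add_noise(img: AnnotatedImage, rng: np.random.Generator, sd: float = 10.0) -> AnnotatedImage:
    noise = rng.normal(0.0, sd, size=img.pixels.shape)
    pix = np.clip(img.pixels.astype(np.float64) + noise, 0, 255).astype(np.uint8)
    return replace(img, pixels=pix, annotations=list(img.annotations))


_TRANSFORMS = ("crop", "jitter", "noise", "rotate")


def _apply(name: str, img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    if name == "crop":
        return _random_crop(img, rng)
    if name == "jitter":
        return _color_jitter(img, rng)
    if name == "noise":
        return _add_noise(img, rng)
    k = int(rng.integers(1, 4))
    return _rotate90(img, k)


def augment_fourfold(samples: list[AnnotatedImage], seed: int = 0) -> list[AnnotatedImage]:
    """Expand a sample list fourfold: each original plus three transformed
    variants, drawn without replacement from {random crop, HSV colour jitter,
    additive Gaussian noise, right-angle rotation}.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    out = []
    for img in samples:
        out.append(img)
        picks = rng.choice(len(_TRANSFORMS), size=3, replace=False)
        for t in picks:
            out.append(_apply(_TRANSFORMS[t], img, rng))
    return out
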