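"""Synthetic paddy scenes.

Emulates the statistical structure of UAV rice-field tiles for desk-scale
work: a green row-crop canvas with stripe texture and pixel noise, elongated
brown field-ridge bands spanning the scene, small bright single
barnyard-grass plants placed between the ridges, and large dark continuous
barnyard-grass patches.  Default object size ranges are chosen so single
plants fall in the COCO small/medium strata and patches and ridges in the
large stratum on a 600 px canvas.  Scenes are exactly reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AnnotatedImage, BoxAnnotation

# per-class render colours (R, G, B): background paddy green, ridge earth
# brown, vivid young single plants, saturated dark weed patches
BACKGROUND = (72, 124, 58)
RIDGE_COLOR = (148, 118, 84)
SINGLE_COLOR = (118, 196, 74)
PATCH_COLOR = (36, 92, 30)


@dataclass(frozen=True)
class SyntheticSceneConfig:
    canvas_size: int = 600
    n_single: int = 5
    n_patch: int = 1
    n_ridge: int = 2
    single_side: tuple = (12, 90)  # small + medium strata at 600 px
    patch_side: tuple = (120, 300)  # large stratum
    ridge_thickness: tuple = (30, 60)  # full-width band -> large stratum
    background_texture: int = 20  # row-crop stripe period, px
    noise_sd: float = 6.0
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self):
        if min(self.n_single, self.n_patch, self.n_ridge) < 0:
            raise ValueError("object counts must be >= 0")
        for rng_ in (self.single_side, self.patch_side, self.ridge_thickness):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid size range {rng_}")
        if self.canvas_size < 8:
            raise ValueError("canvas too small")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _mask_bbox(mask: np.ndarray):
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return None
    # half-open pixel box covering the rendered extent
    return (float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def _boxes_overlap(a, b, margin: float = 2.0) -> bool:
    return not (
        a[2] + margin <= b[0]
        or b[2] + margin <= a[0]
        or a[3] + margin <= b[1]
        or b[3] + margin <= a[1]
    )


def generate_scene(cfg: SyntheticSceneConfig) -> AnnotatedImage:
    """Render one annotated scene.

    Annotation boxes are the tight bounding boxes of the rendered blobs.
    Objects that cannot be placed without overlap within the retry budget are
    skipped; the shortfall is reported in the image's ``meta['placement_failures']``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.canvas_size
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = BACKGROUND
    # row-crop stripe texture: darker bands every `background_texture` rows
    rows = np.arange(n)
    stripe = 1.0 - 0.12 * (np.sin(2 * np.pi * rows / max(cfg.background_texture, 2)) > 0.3)
    img *= stripe[:, None, None]

    annotations: list[BoxAnnotation] = []
    failures = 0

    # --- ridges: full-width horizontal bands ------------------------------
    ridge_bands = []  # (y0, y1) rows occupied, for placing singles between
    for _ in range(cfg.n_ridge):
        placed = False
        for _ in range(cfg.max_retries):
            t = int(rng.integers(cfg.ridge_thickness[0], cfg.ridge_thickness[1] + 1))
            if t >= n:
                continue
            y0 = int(rng.integers(0, n - t + 1))
            box = (0.0, float(y0), float(n), float(y0 + t))
            if any(_boxes_overlap(box, b.box, margin=8) for b in annotations):
                continue
            jitter = rng.normal(0, 4, size=(t, n, 3))
            img[y0 : y0 + t] = np.clip(np.array(RIDGE_COLOR) + jitter, 0, 255)
            annotations.append(BoxAnnotation("field_ridge", box))
            ridge_bands.append((y0, y0 + t))
            placed = True
            break
        if not placed:
            failures += 1

    def _row_free(cy: float, r: float) -> bool:
        return all(not (cy + r > y0 and cy - r < y1) for y0, y1 in ridge_bands)

    # --- large continuous patches -----------------------------------------
    for _ in range(cfg.n_patch):
        placed = False
        for _ in range(cfg.max_retries):
            side = rng.uniform(*cfg.patch_side)
            ry, rx = side / 2 * rng.uniform(0.8, 1.0), side / 2 * rng.uniform(0.8, 1.0)
            if 2 * ry >= n or 2 * rx >= n:  # object larger than the canvas
                continue
            cy = rng.uniform(ry, n - ry)
            cx = rng.uniform(rx, n - rx)
            if not _row_free(cy, ry):
                continue
            mask = _ellipse_mask(n, n, cy, cx, ry, rx)
            box = _mask_bbox(mask)
            if box is None or any(_boxes_overlap(box, b.box) for b in annotations):
                continue
            img[mask] = np.array(PATCH_COLOR) + rng.normal(0, 6, size=(int(mask.sum()), 3))
            annotations.append(BoxAnnotation("patch_barnyard_grass", box))
            placed = True
            break
        if not placed:
            failures += 1

    # --- single plants between the ridges ---------------------------------
    for _ in range(cfg.n_single):
        placed = False
        for _ in range(cfg.max_retries):
            side = rng.uniform(*cfg.single_side)
            ry, rx = side / 2, side / 2 * rng.uniform(0.7, 1.0)
            if 2 * ry >= n or 2 * rx >= n:
                continue
            cy = rng.uniform(ry, n - ry)
            cx = rng.uniform(rx, n - rx)
            if not _row_free(cy, ry):  # singles grow between field ridges
                continue
            mask = _ellipse_mask(n, n, cy, cx, ry, rx)
            box = _mask_bbox(mask)
            if box is None or any(_boxes_overlap(box, b.box) for b in annotations):
                continue
            img[mask] = np.array(SINGLE_COLOR) + rng.normal(0, 8, size=(int(mask.sum()), 3))
            annotations.append(BoxAnnotation("single_barnyard_grass", box))
            placed = True
            break
        if not placed:
            failures += 1

    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return AnnotatedImage(
        pixels=pixels,
        annotations=annotations,
        source_id=f"synthetic_{cfg.seed}",
        meta={"placement_failures": failures, "config_seed": cfg.seed},
    )


def desk_scene_config(seed: int = 0) -> SyntheticSceneConfig:
    """Desk-scale scene preset: a 64 px canvas with few objects, each spanning
    several feature-map cells so a small CPU-trained model can resolve them.

    Used for fast end-to-end training checks; the 600 px defaults remain the
    faithful emulation of the UAV tiles."""
    return SyntheticSceneConfig(
        canvas_size=64,
        n_single=2,
        n_patch=1,
        n_ridge=1,
        single_side=(8, 16),
        patch_side=(20, 32),
        ridge_thickness=(6, 10),
        background_texture=8,
        noise_sd=4.0,
        seed=seed,
    )


def generate_dataset(
    n_scenes: int, base_config: SyntheticSceneConfig, seed: int = 0
) -> list[AnnotatedImage]:
    """Generate n scenes with per-scene seeds derived from one master seed."""
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_scenes)
    from dataclasses import replace

    return [generate_scene(replace(base_config, seed=int(s))) for s in seeds]
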