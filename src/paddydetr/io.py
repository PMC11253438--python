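"""Annotation file formats: LabelMe JSON in, COCO detection JSON in/out.

LabelMe rectangle and polygon shapes are converted to tight bounding boxes.
COCO boxes are [x, y, width, height]; category ids are 1-based in file and
mapped to the package's 0-based class indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .data import LABELS, LABEL_ALIASES, AnnotatedImage, BoxAnnotation


def _canonical_label(raw: str) -> str:
    if raw not in LABEL_ALIASES:
        raise ValueError(
            f"unknown label {raw!r}; expected one of {sorted(set(LABEL_ALIASES))}"
        )
    return LABEL_ALIASES[raw]


def read_labelme(path) -> AnnotatedImage:
    """Read one LabelMe annotation file into an AnnotatedImage.

    The raster is loaded from the file's imagePath when that file exists next
    to the JSON; otherwise a zero canvas of the declared size is used (the
    geometry is still fully checked)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed LabelMe JSON: {e}") from e
    try:
        h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
    except KeyError as e:
        raise ValueError(f"{path}: missing {e} field") from e
    img_file = path.parent / doc.get("imagePath", "")
    if doc.get("imagePath") and img_file.exists():
        pixels = np.asarray(Image.open(img_file).convert("RGB"))
        if pixels.shape[:2] != (h, w):
            raise ValueError(
                f"{path}: image {img_file.name} is {pixels.shape[1]}x{pixels.shape[0]}, "
                f"JSON declares {w}x{h}"
            )
    else:
        pixels = np.zeros((h, w, 3), dtype=np.uint8)
    anns = []
    for shape in doc.get("shapes", []):
        label = _canonical_label(shape["label"])
        pts = np.asarray(shape["points"], dtype=np.float64)
        if shape.get("shape_type", "polygon") not in ("rectangle", "polygon"):
            raise ValueError(f"{path}: unsupported shape_type {shape['shape_type']!r}")
        x1, y1 = pts[:, 0].min(), pts[:, 1].min()
        x2, y2 = pts[:, 0].max(), pts[:, 1].max()
        if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
            raise ValueError(f"{path}: box ({x1},{y1},{x2},{y2}) outside {w}x{h} image")
        anns.append(BoxAnnotation(label, (x1, y1, x2, y2)))
    return AnnotatedImage(pixels=pixels, annotations=anns, source_id=path.stem)


def coco_categories() -> list[dict]:
    return [{"id": i + 1, "name": name} for i, name in enumerate(LABELS)]


def write_coco(samples: list[AnnotatedImage], path, write_images: bool = False) -> dict:
    """Write a COCO detection ground-truth file; returns the document.

    With write_images=True the rasters are saved as PNGs next to the JSON.
    """
    path = Path(path)
    images, annotations = [], []
    ann_id = 1
    for img_id, img in enumerate(samples, start=1):
        file_name = f"{img.source_id or f'image_{img_id}'}.png"
        images.append(
            {"id": img_id, "file_name": file_name, "width": img.width, "height": img.height}
        )
        if write_images:
            Image.fromarray(img.pixels).save(path.parent / file_name)
        for ann in img.annotations:
            x1, y1, x2, y2 = ann.box
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": ann.label_index + 1,
                    "bbox": [x1, y1, x2 - x1, y2 - y1],
                    "area": ann.area,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {"images": images, "annotations": annotations, "categories": coco_categories()}
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))
    return doc


def read_coco(path) -> list[AnnotatedImage]:
    """Read a COCO ground-truth file back into AnnotatedImages.

    Rasters are loaded from the referenced files when present, else zeros.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed COCO JSON: {e}") from e
    cat_map = {}
    for cat in doc["categories"]:
        name = _canonical_label(cat["name"])
        cat_map[cat["id"]] = name
    by_image: dict[int, list] = {img["id"]: [] for img in doc["images"]}
    for ann in doc["annotations"]:
        x, y, w, h = ann["bbox"]
        label = cat_map[ann["category_id"]]
        by_image[ann["image_id"]].append(BoxAnnotation(label, (x, y, x + w, y + h)))
    out = []
    for img in doc["images"]:
        img_file = path.parent / img["file_name"]
        if img_file.exists():
            pixels = np.asarray(Image.open(img_file).convert("RGB"))
        else:
            pixels = np.zeros((img["height"], img["width"], 3), dtype=np.uint8)
        out.append(
            AnnotatedImage(
                pixels=pixels,
                annotations=by_image[img["id"]],
                source_id=Path(img["file_name"]).stem,
            )
        )
    return out


def write_coco_results(detections: list[list[tuple]], path) -> list[dict]:
    """Write COCO results JSON: per image, a list of (class_index, score, xyxy box)."""
    path = Path(path)
    rows = []
    for img_id, dets in enumerate(detections, start=1):
        for cls, score, box in dets:
            x1, y1, x2, y2 = box
            rows.append(
                {
                    "image_id": img_id,
                    "category_id": int(cls) + 1,
                    "bbox": [float(x1), float(y1), float(x2 - x1), float(y2 - y1)],
                    "score": float(score),
                }
            )
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(rows))
    return rows


def read_coco_results(path, n_images: int) -> list[list[tuple]]:
    rows = json.loads(Path(path).read_text())
    out: list[list[tuple]] = [[] for _ in range(n_images)]
    for r in rows:
        x, y, w, h = r["bbox"]
        out[r["image_id"] - 1].append(
            (int(r["category_id"]) - 1, float(r["score"]), (x, y, x + w, y + h))
        )
    return out
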