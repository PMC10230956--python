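"""COCO-format dataset containers and JSON round-tripping.

Instance masks are stored in memory as full-size boolean rasters and
serialised either as uncompressed COCO run-length encodings (column-major
counts, bit-exact round trip) or as polygon outlines (within one pixel at
the boundary).  Dataset integrity (unique ids, resolvable image references)
is validated on read and on construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure
from skimage.draw import polygon as draw_polygon


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class InstanceAnnotation:
    """One ground-truth instance: visible-region mask plus derived box/area.

    The box is the tight bounding box of the mask, 0-based with half-open
    convention (x_min, y_min, x_max, y_max); ``area`` is the mask pixel
    count.  Those invariants are enforced at construction.
    """

    mask: np.ndarray
    category_id: int = 1
    id: int = 0
    box: tuple[float, float, float, float] = field(init=False)
    area: int = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        ys, xs = np.nonzero(self.mask)
        if ys.size == 0:
            raise ValueError("mask must be nonempty")
        self.box = (float(xs.min()), float(ys.min()),
                    float(xs.max()) + 1.0, float(ys.max()) + 1.0)
        self.area = int(ys.size)


@dataclass
class ImageRecord:
    id: int
    file_name: str
    height: int
    width: int
    pixels: np.ndarray | None = None  # (H, W, 3) uint8 when in memory


@dataclass
class CocoDataset:
    images: list[ImageRecord]
    annotations: list[tuple[int, InstanceAnnotation]]  # (image_id, annotation)
    categories: list[tuple[int, str]] = field(default_factory=lambda: [(1, "apple")])

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        img_ids = [im.id for im in self.images]
        if len(set(img_ids)) != len(img_ids):
            raise ValueError("duplicate image ids")
        ann_ids = [a.id for _, a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise ValueError("duplicate annotation ids")
        known = set(img_ids)
        for image_id, ann in self.annotations:
            if image_id not in known:
                raise ValueError(f"annotation {ann.id} references unknown image {image_id}")

    def annotations_for(self, image_id: int) -> list[InstanceAnnotation]:
        return [a for iid, a in self.annotations if iid == image_id]

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# run-length encoding (COCO uncompressed, column-major)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed COCO RLE.

    Counts alternate runs of 0s and 1s over the mask flattened in Fortran
    (column-major) order, starting with zeros.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = mask.flatten(order="F").astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    total = int(np.sum(counts))
    if total != h * w:
        raise ValueError(f"RLE counts sum to {total}, expected {h * w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------------------
# polygon encoding
# ---------------------------------------------------------------------------

def polygon_encode(mask: np.ndarray) -> list[list[float]]:
    """Trace mask outlines as COCO polygons ([x0, y0, x1, y1, ...] lists).

    Disconnected components become separate polygons.  Interior holes are
    not representable in polygon mode; use RLE for masks with holes.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        ys = contour[:, 0] - 1.0
        xs = contour[:, 1] - 1.0
        if len(xs) < 3:
            continue
        poly = np.empty(2 * len(xs))
        poly[0::2] = xs
        poly[1::2] = ys
        polys.append(poly.tolist())
    return polys


def polygon_decode(polys: list[list[float]], height: int, width: int) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    for poly in polys:
        xs = np.asarray(poly[0::2])
        ys = np.asarray(poly[1::2])
        rr, cc = draw_polygon(ys, xs, shape=(height, width))
        mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def write_coco(dataset: CocoDataset, path: str | Path, *,
               mask_format: str = "rle") -> None:
    """Serialise a dataset to a standard COCO instance-annotation JSON file."""
    if mask_format not in ("rle", "polygon"):
        raise ValueError(f"unknown mask format {mask_format!r}")
    doc = {
        "images": [
            {"id": im.id, "file_name": im.file_name,
             "height": im.height, "width": im.width}
            for im in dataset.images
        ],
        "annotations": [],
        "categories": [
            {"id": cid, "name": name, "supercategory": "fruit"}
            for cid, name in dataset.categories
        ],
    }
    for image_id, ann in dataset.annotations:
        x0, y0, x1, y1 = ann.box
        seg = rle_encode(ann.mask) if mask_format == "rle" else polygon_encode(ann.mask)
        doc["annotations"].append({
            "id": ann.id,
            "image_id": image_id,
            "category_id": ann.category_id,
            "segmentation": seg,
            "bbox": [x0, y0, x1 - x0, y1 - y0],
            "area": ann.area,
            "iscrowd": 0,
        })
    Path(path).write_text(json.dumps(doc))


def read_coco(path: str | Path) -> CocoDataset:
    """Parse a COCO JSON file back into a :class:`CocoDataset`.

    Malformed JSON or dangling references raise with the offending record
    named.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed COCO JSON at {path}: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"COCO JSON missing top-level key {key!r}")
    images = [ImageRecord(int(rec["id"]), rec["file_name"],
                          int(rec["height"]), int(rec["width"]))
              for rec in doc["images"]]
    sizes = {im.id: (im.height, im.width) for im in images}
    annotations: list[tuple[int, InstanceAnnotation]] = []
    for rec in doc["annotations"]:
        image_id = int(rec["image_id"])
        if image_id not in sizes:
            raise ValueError(
                f"annotation id={rec.get('id')} references missing image {image_id}")
        h, w = sizes[image_id]
        seg = rec["segmentation"]
        if isinstance(seg, dict):
            mask = rle_decode(seg)
            if mask.shape != (h, w):
                raise ValueError(f"annotation id={rec.get('id')} RLE size mismatch")
        else:
            mask = polygon_decode(seg, h, w)
        ann = InstanceAnnotation(mask, category_id=int(rec["category_id"]),
                                 id=int(rec["id"]))
        annotations.append((image_id, ann))
    categories = [(int(c["id"]), c["name"]) for c in doc["categories"]]
    return CocoDataset(images=images, annotations=annotations, categories=categories)
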