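"""Procedural orchard-scene generator with per-instance ground truth.

Green-fruit segmentation is hard because the fruit is nearly the same
colour as the canopy ("green on green"), fruits overlap each other, and
foliage occludes them.  This module emulates those conditions: elliptical
low-chroma fruits placed on a textured green background at three size
strata, with leaf-shaped occluders drawn on top and carved out of the fruit
masks.  Every scene is generated deterministically from (config.seed,
image index) and carries exact visible-region masks, so the generator
doubles as the package's ground-truth oracle for training and evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import rotate as sk_rotate

from .coco_io import CocoDataset, ImageRecord, InstanceAnnotation

logger = logging.getLogger(__name__)

# COCO area convention at the reference image scale (600x400, the nominal
# capture resolution): small < 32^2, medium < 96^2.  Cutoffs scale with
# image area so strata keep their meaning on reduced-size scenes.
_REF_AREA = 600 * 400
_SMALL_CUT = 32 ** 2
_MEDIUM_CUT = 96 ** 2


def area_cutoffs(image_size: tuple[int, int]) -> tuple[float, float]:
    """(small/medium, medium/large) pixel-area cutoffs for an image size."""
    scale = (image_size[0] * image_size[1]) / _REF_AREA
    return _SMALL_CUT * scale, _MEDIUM_CUT * scale


def area_stratum(area: float, image_size: tuple[int, int]) -> str:
    lo, hi = area_cutoffs(image_size)
    if area < lo:
        return "small"
    if area < hi:
        return "medium"
    return "large"


@dataclass
class SceneConfig:
    """Parameters of the synthetic orchard scene distribution.

    ``contrast_delta`` bounds the per-channel difference (0-255 scale)
    between a fruit's mean colour and the mean of its local background —
    the dial that makes scenes "green on green".  ``overlap_allowance`` is
    the maximum pairwise mask IoU accepted at placement time;
    ``occluder_density`` is the expected number of foliage polygons drawn
    over the fruit layer.
    """

    image_size: tuple[int, int] = (400, 600)  # (height, width)
    n_fruits_range: tuple[int, int] = (3, 8)
    fruit_radius_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"small": (6.0, 16.0),
                                 "medium": (21.0, 48.0),
                                 "large": (64.0, 80.0)})
    scale_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)
    contrast_delta: float = 25.0
    occluder_density: float = 3.0
    overlap_allowance: float = 0.25
    seed: int = 0
    n_categories: int = 1

    def __post_init__(self):
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image dims must be >= 64")
        if abs(sum(self.scale_mix) - 1.0) > 1e-6:
            raise ValueError("scale_mix must sum to 1")
        prev_hi = 0.0
        for key in ("small", "medium", "large"):
            lo, hi = self.fruit_radius_ranges[key]
            if not (0 < lo < hi):
                raise ValueError(f"radius interval for {key} must be positive and ordered")
            if lo <= prev_hi:
                raise ValueError("radius intervals must be disjoint and ordered")
            prev_hi = hi
        if not (0 <= self.overlap_allowance <= 1):
            raise ValueError("overlap_allowance must be in [0, 1]")
        if self.n_fruits_range[0] > self.n_fruits_range[1] or self.n_fruits_range[0] < 0:
            raise ValueError("invalid n_fruits_range")


def tiny_scene_config(seed: int = 0) -> SceneConfig:
    """Reduced-scale scene distribution for desk-size (128 px) experiments."""
    return SceneConfig(
        image_size=(128, 128),
        n_fruits_range=(1, 3),
        fruit_radius_ranges={"small": (5.0, 9.0), "medium": (12.0, 24.0),
                             "large": (27.0, 34.0)},
        scale_mix=(0.2, 0.6, 0.2),
        contrast_delta=25.0,
        occluder_density=1.5,
        overlap_allowance=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scene synthesis
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Textured green canopy backdrop (float, 0-255)."""
    base = np.array([62.0, 108.0, 55.0]) + rng.normal(0, 8, size=3)
    img = np.empty((h, w, 3), dtype=np.float64)
    # low-frequency luminance mottle shared by channels + per-channel grain
    mottle = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), sigma=min(h, w) / 8)
    mottle = mottle / (np.abs(mottle).max() + 1e-9) * 18.0
    for c in range(3):
        grain = ndimage.gaussian_filter(rng.normal(0, 6, size=(h, w)), sigma=1.5)
        img[..., c] = base[c] + mottle + grain
    return img


def _fruit_geometry(rng: np.random.Generator, cfg: SceneConfig,
                    stratum: str) -> tuple[float, float, float]:
    lo, hi = cfg.fruit_radius_ranges[stratum]
    r = rng.uniform(lo, hi)
    aspect = rng.uniform(0.75, 1.0)
    theta = rng.uniform(0, np.pi)
    return r, r * aspect, theta


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return inter / np.logical_or(a, b).sum()


def _draw_occluder(rng: np.random.Generator, img: np.ndarray,
                   h: int, w: int) -> np.ndarray:
    """Paint one leaf-like occluder; returns its raster mask."""
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    length = rng.uniform(0.04, 0.14) * max(h, w)
    width = length * rng.uniform(0.25, 0.5)
    theta = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(cy, cx, length, width, shape=(h, w), rotation=theta)
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    color = np.array([38.0, 82.0, 40.0]) + rng.normal(0, 6, size=3)
    img[mask] = color + rng.normal(0, 3, size=(mask.sum(), 3))
    return mask


def generate_scene(config: SceneConfig, index: int
                   ) -> tuple[np.ndarray, list[InstanceAnnotation]]:
    """Render scene ``index`` of the configured distribution.

    Returns an (H, W, 3) uint8 image and visible-region annotations sorted
    by decreasing area.  Placement that cannot satisfy the overlap
    allowance within the retry budget silently yields fewer fruits; fully
    occluded fruits are dropped.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    h, w = config.image_size
    img = _background(rng, h, w)

    n_fruits = int(rng.integers(config.n_fruits_range[0], config.n_fruits_range[1] + 1))
    strata = rng.choice(3, size=n_fruits, p=config.scale_mix)
    masks: list[np.ndarray] = []
    cats: list[int] = []
    for s_idx in strata:
        stratum = ("small", "medium", "large")[s_idx]
        placed = False
        for _ in range(30):  # bounded retry budget
            ra, rb, theta = _fruit_geometry(rng, config, stratum)
            cy = rng.uniform(ra, h - ra) if h > 2 * ra else h / 2
            cx = rng.uniform(ra, w - ra) if w > 2 * ra else w / 2
            rr, cc = draw_ellipse(cy, cx, ra, rb, shape=(h, w), rotation=theta)
            cand = np.zeros((h, w), dtype=bool)
            cand[rr, cc] = True
            if not cand.any():
                continue
            if all(_mask_iou(cand, m) <= config.overlap_allowance for m in masks):
                placed = True
                break
        if not placed:
            continue
        # paint the fruit: hue-matched to the local backdrop, offset bounded
        # by contrast_delta per channel (sampled inside 80% of the budget so
        # pixel grain cannot push the mean over)
        dil = ndimage.binary_dilation(cand, iterations=max(3, int(ra * 0.3)))
        ring = dil & ~cand
        local_mean = img[ring].mean(axis=0) if ring.any() else img.mean(axis=(0, 1))
        offset = rng.uniform(-0.8, 0.8, size=3) * config.contrast_delta
        ys, xs = np.nonzero(cand)
        # gentle radial shading, zero-mean so the contrast bound is kept
        rad = np.hypot(ys - cy, xs - cx) / max(ra, 1.0)
        shade = (0.5 - rad) * 6.0
        shade -= shade.mean()
        pix = local_mean[None, :] + offset[None, :] + shade[:, None]
        pix = pix + rng.normal(0, 1.5, size=pix.shape)
        img[ys, xs] = pix
        masks.append(cand)
        cats.append(int(rng.integers(1, config.n_categories + 1)))

    # foliage occluders: drawn after fruits, carved out of every fruit mask
    n_occ = int(rng.poisson(config.occluder_density))
    for _ in range(n_occ):
        occ = _draw_occluder(rng, img, h, w)
        for m in masks:
            m &= ~occ

    annotations = []
    for ann_id, (m, cat) in enumerate(zip(masks, cats), start=1):
        if not m.any():
            continue
        annotations.append(InstanceAnnotation(m, category_id=cat, id=ann_id))
    annotations.sort(key=lambda a: -a.area)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return image, annotations


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Per-transform firing probabilities and ranges.

    Geometric transforms move image and masks identically; photometric ones
    touch the image only.  Rotation angles default to right angles, which
    are pixel-exact; arbitrary angles are supported (nearest-neighbour mask
    resampling).
    """

    p_shift: float = 0.5
    max_shift: float = 0.1            # fraction of image extent
    p_hflip: float = 0.5
    p_vflip: float = 0.2
    p_rotate: float = 0.3
    angles: tuple[float, ...] = (90.0, 180.0, 270.0)
    p_photometric: float = 0.8
    brightness: float = 0.25
    contrast: float = 0.25
    saturation: float = 0.25


def _shift(arr: np.ndarray, dy: int, dx: int, order_last: bool) -> np.ndarray:
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def augment(image: np.ndarray, annotations: list[InstanceAnnotation],
            seed: int | np.random.Generator,
            config: AugmentConfig | None = None
            ) -> tuple[np.ndarray, list[InstanceAnnotation]]:
    """Randomly perturb a scene, keeping image and ground truth consistent.

    Each transform fires independently with its configured probability.
    Boxes are recomputed from the transformed masks; instances whose masks
    become empty (shifted out of frame) are dropped with a logged notice.
    """
    cfg = config or AugmentConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = image.astype(np.float64)
    masks = [a.mask.copy() for a in annotations]
    cats = [a.category_id for a in annotations]
    ids = [a.id for a in annotations]
    h, w = img.shape[:2]

    if rng.random() < cfg.p_shift:
        dy = int(rng.integers(-int(cfg.max_shift * h), int(cfg.max_shift * h) + 1))
        dx = int(rng.integers(-int(cfg.max_shift * w), int(cfg.max_shift * w) + 1))
        img = _shift(img, dy, dx, True)
        masks = [_shift(m, dy, dx, False) for m in masks]
    if rng.random() < cfg.p_hflip:
        img = img[:, ::-1].copy()
        masks = [m[:, ::-1].copy() for m in masks]
    if rng.random() < cfg.p_vflip:
        img = img[::-1].copy()
        masks = [m[::-1].copy() for m in masks]
    if rng.random() < cfg.p_rotate:
        angle = float(rng.choice(cfg.angles))
        if angle % 90 == 0 and h == w:
            k = int(angle // 90) % 4
            img = np.rot90(img, k).copy()
            masks = [np.rot90(m, k).copy() for m in masks]
        else:
            img = sk_rotate(img / 255.0, angle, preserve_range=True) * 255.0
            masks = [sk_rotate(m.astype(float), angle, order=0) > 0.5 for m in masks]

    if rng.random() < cfg.p_photometric:
        b = 1.0 + rng.uniform(-cfg.brightness, cfg.brightness)
        c = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        s = 1.0 + rng.uniform(-cfg.saturation, cfg.saturation)
        img = img * b
        mean = img.mean()
        img = (img - mean) * c + mean
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (img - gray) * s

    out_annotations = []
    for m, cat, aid in zip(masks, cats, ids):
        if not m.any():
            logger.info("augment: instance %d dropped (mask empty after transform)", aid)
            continue
        out_annotations.append(InstanceAnnotation(m, category_id=cat, id=aid))
    return np.clip(img, 0, 255).astype(np.uint8), out_annotations


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(config: SceneConfig, n_images: int, split_ratio: float = 0.7
                  ) -> tuple[CocoDataset, CocoDataset]:
    """Generate ``n_images`` scenes and split them train/validation.

    The split is disjoint by image id; the training set receives
    ``round(n_images * split_ratio)`` images (e.g. 1361 at ratio 0.7 gives
    953 train / 408 validation).
    """
    if n_images < 2:
        raise ValueError("need at least 2 images to split")
    if not (0.0 < split_ratio < 1.0):
        raise ValueError("split_ratio must be in (0, 1)")
    n_train = int(round(n_images * split_ratio))
    n_train = min(max(n_train, 1), n_images - 1)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0C0]))
    order = rng.permutation(n_images)
    train_ids = set(int(i) for i in order[:n_train])

    splits = {"train": ([], []), "val": ([], [])}
    next_ann_id = {"train": 1, "val": 1}
    for i in range(n_images):
        image, annotations = generate_scene(config, i)
        key = "train" if i in train_ids else "val"
        images, anns = splits[key]
        h, w = config.image_size
        images.append(ImageRecord(id=i, file_name=f"scene_{i:05d}.png",
                                  height=h, width=w, pixels=image))
        for ann in annotations:
            ann = InstanceAnnotation(ann.mask, category_id=ann.category_id,
                                     id=next_ann_id[key])
            next_ann_id[key] += 1
            anns.append((i, ann))
    categories = [(c, "apple" if c == 1 else f"class_{c}")
                  for c in range(1, config.n_categories + 1)]
    train = CocoDataset(images=splits["train"][0], annotations=splits["train"][1],
                        categories=categories)
    val = CocoDataset(images=splits["val"][0], annotations=splits["val"][1],
                      categories=categories)
    return train, val
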