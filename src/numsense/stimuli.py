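"""Stimulus construction: mosaics, area-matched ellipse scenes, and variants.

Scenes place ellipse-clipped objects on a black canvas divided into a 4x4
virtual grid; per-item scale factors are jittered within +/-25% of the mean
size and the candidate combination whose total area best matches the preset
target is kept, so the summed object area is approximately constant across
numerosities 1-7 while item sizes vary naturally. Degraded variants
(white-noise overlay, foreground-only clip, noise-filled clip, background-
only, phase scrambling) dissect which image content carries the numerical
information.

Conventions: 0-based pixel coordinates with the origin at the top-left,
half-open boxes; "white noise" is i.i.d. uniform 8-bit per channel; the
soft ellipse edge comes from convolving the binary ellipse mask with a
normalized fade_kernel x fade_kernel Gaussian (sigma = fade_kernel / 6) and
masking to the ellipse interior, so pixels outside the ellipse stay exactly
black while the rim ramps smoothly to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._utils import rng_from, spawn_seeds
from .config import SceneLayoutConfig

__all__ = [
    "BBox", "ImageStim", "ScaleSolution",
    "compose_mosaic", "clip_ellipse", "solve_scales", "compose_ellipse_scene",
    "make_scene", "make_natural_scene", "build_mosaic_dataset",
    "build_scene_dataset", "add_noise", "apply_region_variant",
    "phase_scramble", "white_noise", "gaussian_kernel", "soft_ellipse_weight",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box: top-left (x, y), extents (w, h), half-open."""

    x: int
    y: int
    w: int
    h: int
    category_label: str = ""

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box extents must be positive, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"box offsets must be non-negative, got x={self.x}, y={self.y}")

    def validate_inside(self, image: np.ndarray) -> None:
        H, W = image.shape[:2]
        if self.x + self.w > W or self.y + self.h > H:
            raise ValueError(f"{self} does not lie inside a {H}x{W} image")

    def crop(self, image: np.ndarray) -> np.ndarray:
        self.validate_inside(image)
        return image[self.y:self.y + self.h, self.x:self.x + self.w]


@dataclass
class ImageStim:
    """A stimulus image with its numerosity and construction provenance."""

    pixels: np.ndarray
    item_count: int
    boxes: list = field(default_factory=list)
    variant: str = "original"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)
        if self.item_count < 1:
            raise ValueError("item_count must be >= 1")


def white_noise(shape, rng) -> np.ndarray:
    return rng.integers(0, 256, size=shape, dtype=np.int64).astype(np.uint8)


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------

def compose_mosaic(subblocks, same_category: bool = False,
                   noise_patches: bool = False, seed=0) -> ImageStim:
    """Grid-like mosaic of 1-7 sub-block images on black background.

    Cell size is the maximum sub-block height/width, so the canvas dimensions
    are multiples of it; packing is row-major with black filler for
    non-square counts. ``noise_patches`` replaces each sub-block's content
    with white noise of the same shape.
    """
    if not subblocks:
        raise ValueError("mosaic needs at least one sub-block")
    if len(subblocks) > 7:
        raise ValueError(f"mosaic supports 1-7 sub-blocks, got {len(subblocks)}")
    blocks = [np.asarray(b) for b in subblocks]
    rng = rng_from(seed)
    if noise_patches:
        blocks = [white_noise(b.shape, rng) for b in blocks]
    max_h = max(b.shape[0] for b in blocks)
    max_w = max(b.shape[1] for b in blocks)
    n = len(blocks)
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    canvas = np.zeros((rows * max_h, cols * max_w, 3), dtype=np.uint8)
    boxes = []
    for k, b in enumerate(blocks):
        r, c = divmod(k, cols)
        y, x = r * max_h, c * max_w
        canvas[y:y + b.shape[0], x:x + b.shape[1]] = b[..., :3] if b.ndim == 3 \
            else np.stack([b] * 3, axis=-1)
        boxes.append(BBox(x=x, y=y, w=b.shape[1], h=b.shape[0]))
    variant = "noise_patch" if noise_patches else ("mosaic_same" if same_category
                                                   else "mosaic_diff")
    return ImageStim(pixels=canvas, item_count=n, boxes=boxes, variant=variant,
                     provenance={"seed": int(seed)})


# ---------------------------------------------------------------------------
# ellipse clipping with soft edges
# ---------------------------------------------------------------------------

def gaussian_kernel(size: int) -> np.ndarray:
    """Normalized size x size Gaussian kernel with sigma = size / 6."""
    sigma = size / 6.0
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _ellipse_mask(h: int, w: int) -> np.ndarray:
    """Binary mask of the ellipse inscribed in an h x w box."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = w / 2.0, h / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2) <= 1.0


def soft_ellipse_weight(h: int, w: int, fade_kernel: int) -> np.ndarray:
    """Attenuation map: 1 deep inside the inscribed ellipse, Gaussian ramp at
    the rim, exactly 0 outside."""
    mask = _ellipse_mask(h, w)
    kern = gaussian_kernel(fade_kernel)
    smoothed = ndimage.convolve(mask.astype(float), kern, mode="constant", cval=0.0)
    return smoothed * mask


def clip_ellipse(image: np.ndarray, box: BBox, fade_kernel: int = 15) -> np.ndarray:
    """Elliptical patch cut from a bounding box with a soft faded rim.

    Returns a box-sized uint8 patch: content inside the inscribed ellipse,
    black outside, rim attenuated by the inverted-Gaussian ramp.
    """
    if box.w < fade_kernel or box.h < fade_kernel:
        raise ValueError(f"degenerate box: extents ({box.w}x{box.h}) smaller than "
                         f"fade_kernel {fade_kernel}")
    crop = box.crop(np.asarray(image)).astype(float)
    weight = soft_ellipse_weight(box.h, box.w, fade_kernel)
    out = crop * weight[..., None] if crop.ndim == 3 else crop * weight
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# area-matched scale solving
# ---------------------------------------------------------------------------

@dataclass
class ScaleSolution:
    factors: np.ndarray       # per-item area multipliers of the base areas
    areas: np.ndarray         # resulting per-item areas (pixels^2)
    achieved_total: float
    target_total: float
    feasible: bool


def solve_scales(n_items: int, cfg: SceneLayoutConfig, base_areas=None,
                 seed=None) -> ScaleSolution:
    """Pick per-item scale factors whose summed area best matches the target.

    The mean item size is the target total area divided by the item count;
    ``n_candidates`` random factor combinations within +/-``scale_jitter``
    are evaluated and the one minimizing the absolute deviation from the
    target total is returned (single items take the mean size directly).
    When explicit ``base_areas`` place the target outside the reachable
    band, the best-effort combination is returned with ``feasible=False``.
    """
    if not 1 <= n_items <= cfg.grid_rows * cfg.grid_cols:
        raise ValueError(f"n_items must be in [1, {cfg.grid_rows * cfg.grid_cols}]")
    mean_area = cfg.target_total_area / n_items
    if base_areas is None:
        base_areas = np.full(n_items, mean_area)
    else:
        base_areas = np.asarray(base_areas, dtype=float)
        if base_areas.shape != (n_items,):
            raise ValueError(f"need {n_items} base areas, got {base_areas.shape}")
    if n_items == 1 or cfg.scale_jitter == 0:
        factors = np.ones(n_items) * (mean_area * n_items / base_areas.sum())
        areas = factors * base_areas
        return ScaleSolution(factors=factors, areas=areas,
                             achieved_total=float(areas.sum()),
                             target_total=cfg.target_total_area, feasible=True)
    rng = rng_from(cfg.seed if seed is None else seed)
    j = cfg.scale_jitter
    cand = rng.uniform(1 - j, 1 + j, size=(cfg.n_candidates, n_items))
    totals = cand @ base_areas
    best = int(np.argmin(np.abs(totals - cfg.target_total_area)))
    factors = cand[best]
    areas = factors * base_areas
    achieved = float(areas.sum())
    lo, hi = (1 - j) * base_areas.sum(), (1 + j) * base_areas.sum()
    feasible = lo <= cfg.target_total_area <= hi
    return ScaleSolution(factors=factors, areas=areas, achieved_total=achieved,
                         target_total=cfg.target_total_area, feasible=feasible)


# ---------------------------------------------------------------------------
# scene composition
# ---------------------------------------------------------------------------

def _nonblack(img: np.ndarray) -> np.ndarray:
    return img.sum(axis=-1) > 0 if img.ndim == 3 else img > 0


def compose_ellipse_scene(patches, cfg: SceneLayoutConfig, seed=0) -> ImageStim:
    """Place 1-7 patches into distinct grid cells with non-overlap jitter.

    Each patch is anchored to its own virtual grid cell: the patch center is
    jittered uniformly within the cell (clamped so the patch stays on
    canvas), and a placement is accepted only if its non-black support is
    disjoint from everything already placed. After ``max_retries`` failed
    jitters the composition errors, naming the failing item.
    """
    n = len(patches)
    n_cells = cfg.grid_rows * cfg.grid_cols
    if not 1 <= n <= min(7, n_cells):
        raise ValueError(f"scene needs 1-{min(7, n_cells)} patches, got {n}")
    rng = rng_from(seed)
    size = cfg.canvas_size
    cell = size // cfg.grid_rows
    arrays = [np.asarray(p) for p in patches]
    for k, p in enumerate(arrays):
        if p.shape[0] > size or p.shape[1] > size:
            raise ValueError(f"item {k}: patch ({p.shape[0]}x{p.shape[1]}) larger "
                             f"than canvas ({size})")
    supports = [_nonblack(p) for p in arrays]
    last_failed = 0
    for _ in range(cfg.max_retries):
        # fresh cell assignment each attempt: items larger than a cell can
        # only coexist when their cells are far enough apart
        cells = rng.choice(n_cells, size=n, replace=False)
        canvas = np.zeros((size, size, 3), dtype=np.uint8)
        occupied = np.zeros((size, size), dtype=bool)
        boxes = []
        ok = True
        for k, (patch, support, c) in enumerate(zip(arrays, supports, cells)):
            ph, pw = patch.shape[:2]
            row, col = divmod(int(c), cfg.grid_cols)
            placed = False
            for _ in range(30):
                cy = rng.uniform(row * cell, (row + 1) * cell)
                cx = rng.uniform(col * cell, (col + 1) * cell)
                y = int(round(np.clip(cy - ph / 2, 0, size - ph)))
                x = int(round(np.clip(cx - pw / 2, 0, size - pw)))
                region = occupied[y:y + ph, x:x + pw]
                if not np.any(region & support):
                    canvas[y:y + ph, x:x + pw] = np.maximum(canvas[y:y + ph, x:x + pw],
                                                            patch[..., :3])
                    occupied[y:y + ph, x:x + pw] |= support
                    boxes.append(BBox(x=x, y=y, w=pw, h=ph))
                    placed = True
                    break
            if not placed:
                last_failed, ok = k, False
                break
        if ok:
            # per-item support sizes let a consumer verify disjointness:
            # their sum equals the union support iff no two items overlap
            return ImageStim(pixels=canvas, item_count=n, boxes=boxes,
                             variant="ellipse_scene",
                             provenance={"seed": int(seed),
                                         "cells": [int(c) for c in cells],
                                         "support_counts": [int(s.sum())
                                                            for s in supports]})
    raise RuntimeError(f"could not place item {last_failed} without overlap after "
                       f"{cfg.max_retries} layout attempts")


def make_scene(images, cfg: SceneLayoutConfig, seed=0, noise_fill: bool = False,
               variant: str | None = None) -> ImageStim:
    """Clip, area-match, and compose source object images into one scene."""
    from skimage.transform import resize

    n = len(images)
    seeds = spawn_seeds(int(seed), 3)
    sol = solve_scales(n, cfg, seed=seeds[0])
    rng = rng_from(seeds[1])
    patches = []
    for img, area in zip(images, sol.areas):
        img = np.asarray(img)
        h, w = img.shape[:2]
        if noise_fill:
            img = white_noise((h, w, 3), rng)
        # inscribed-ellipse area of the full frame is pi/4 * w * h
        ratio = math.sqrt(area / (math.pi / 4.0 * w * h))
        th = max(cfg.fade_kernel, int(round(h * ratio)))
        tw = max(cfg.fade_kernel, int(round(w * ratio)))
        scaled = np.clip(np.round(resize(img.astype(float), (th, tw), mode="reflect",
                                         anti_aliasing=True)), 0, 255).astype(np.uint8)
        patches.append(clip_ellipse(scaled, BBox(0, 0, tw, th), cfg.fade_kernel))
    stim = compose_ellipse_scene(patches, cfg, seed=seeds[2])
    stim.variant = variant or ("noise_patch" if noise_fill else "ellipse_scene")
    stim.provenance.update({"target_total_area": cfg.target_total_area,
                            "achieved_total_area": sol.achieved_total})
    return stim


def make_natural_scene(images, cfg: SceneLayoutConfig, seed=0,
                       size_range: tuple[float, float] = (0.35, 1.3)) -> ImageStim:
    """Compose a scene whose object sizes do not depend on the item count.

    Unlike :func:`make_scene`, the total object area here grows roughly in
    proportion to the number of items — the statistics of ordinary
    photographs, where adding an object adds its area. Per-item areas are
    drawn uniformly from ``size_range`` times half a grid-cell's area.
    """
    from skimage.transform import resize

    seeds = spawn_seeds(int(seed), 2)
    rng = rng_from(seeds[0])
    base_area = 0.5 * (cfg.canvas_size / cfg.grid_rows) ** 2
    patches = []
    for img in images:
        img = np.asarray(img)
        h, w = img.shape[:2]
        area = base_area * rng.uniform(*size_range)
        ratio = math.sqrt(area / (math.pi / 4.0 * w * h))
        th = max(cfg.fade_kernel, int(round(h * ratio)))
        tw = max(cfg.fade_kernel, int(round(w * ratio)))
        scaled = np.clip(np.round(resize(img.astype(float), (th, tw), mode="reflect",
                                         anti_aliasing=True)), 0, 255).astype(np.uint8)
        patches.append(clip_ellipse(scaled, BBox(0, 0, tw, th), cfg.fade_kernel))
    stim = compose_ellipse_scene(patches, cfg, seed=seeds[1])
    stim.variant = "natural_scene"
    return stim


def build_mosaic_dataset(images, labels, n_items: int, n_scenes: int, seed=0,
                         same_category: bool = False,
                         noise_patches: bool = False) -> list[ImageStim]:
    """A pool of mosaic pictures with ``n_items`` sub-blocks each.

    Sub-blocks are drawn from distinct categories unless ``same_category``;
    ``noise_patches`` swaps every sub-block for white noise of its shape.
    """
    labels = np.asarray(labels)
    cats = np.unique(labels)
    if not same_category and n_items > cats.size:
        raise ValueError(f"{n_items} distinct categories requested, only {cats.size} exist")
    seeds = spawn_seeds(int(seed), n_scenes)
    out = []
    for s in range(n_scenes):
        rng = rng_from(seeds[s])
        if same_category:
            cat = rng.choice(cats)
            pool = np.flatnonzero(labels == cat)
            idx = rng.choice(pool, n_items, replace=n_items > pool.size)
        else:
            chosen = rng.choice(cats, n_items, replace=False)
            idx = np.array([rng.choice(np.flatnonzero(labels == c)) for c in chosen])
        out.append(compose_mosaic([images[i] for i in idx],
                                  same_category=same_category,
                                  noise_patches=noise_patches, seed=seeds[s]))
    return out


def build_scene_dataset(images, labels, n_items: int, n_scenes: int,
                        cfg: SceneLayoutConfig, seed=0,
                        mode: str = "different") -> list[ImageStim]:
    """A pool of composed scenes with ``n_items`` objects each.

    ``mode``: 'different' draws items from distinct categories, 'same' from
    one random category, 'noise' fills the ellipses with white noise,
    'natural' draws distinct categories with count-independent object sizes
    (total area grows with the count, as in ordinary photographs).
    """
    labels = np.asarray(labels)
    cats = np.unique(labels)
    if mode == "different" and n_items > cats.size:
        raise ValueError(f"{n_items} distinct categories requested, only {cats.size} exist")
    seeds = spawn_seeds(int(seed), n_scenes)
    scenes = []
    for s in range(n_scenes):
        rng = rng_from(seeds[s])
        if mode == "same":
            cat = rng.choice(cats)
            idx = rng.choice(np.flatnonzero(labels == cat), n_items,
                             replace=n_items > (labels == cat).sum())
        else:
            chosen = rng.choice(cats, n_items, replace=False)
            idx = np.array([rng.choice(np.flatnonzero(labels == c)) for c in chosen])
        if mode == "natural":
            scenes.append(make_natural_scene([images[i] for i in idx], cfg, seed=seeds[s]))
        else:
            scenes.append(make_scene([images[i] for i in idx], cfg, seed=seeds[s],
                                     noise_fill=(mode == "noise")))
    return scenes


# ---------------------------------------------------------------------------
# degraded variants
# ---------------------------------------------------------------------------

def add_noise(image: np.ndarray | ImageStim, weight: float, seed=0) -> ImageStim:
    """Overlay white noise: clip(image + weight * noise) in 8-bit range.

    The standard sweep uses weights 0.5, 1.0, 2.0 and 3.0 (50%-300%), but any
    non-negative weight is accepted; weight 0 returns the image unchanged.
    """
    if weight < 0:
        raise ValueError(f"noise weight must be >= 0, got {weight}")
    pixels = image.pixels if isinstance(image, ImageStim) else np.asarray(image)
    count = image.item_count if isinstance(image, ImageStim) else 1
    boxes = list(image.boxes) if isinstance(image, ImageStim) else []
    if weight == 0:
        out = pixels.copy()
    else:
        rng = rng_from(seed)
        noise = white_noise(pixels.shape, rng).astype(float)
        out = np.clip(pixels.astype(float) + weight * noise, 0, 255)
    return ImageStim(pixels=out, item_count=count, boxes=boxes,
                     variant=f"noise_overlay({weight:g})",
                     provenance={"seed": int(seed), "weight": float(weight)})


def apply_region_variant(image: np.ndarray | ImageStim, boxes, variant: str,
                         fade_kernel: int = 15, seed=0) -> ImageStim:
    """Foreground/background dissection of a boxed image.

    ``clip``: keep the inscribed-ellipse interiors, black elsewhere;
    ``noise_clip``: black outside AND white noise (none of the original)
    inside; ``bbox_cleared``: black out the ellipse interiors, keep the
    background. All edges use the soft Gaussian ramp.
    """
    if not boxes:
        raise ValueError("region variants need at least one bounding box")
    pixels = (image.pixels if isinstance(image, ImageStim) else np.asarray(image)).astype(float)
    count = image.item_count if isinstance(image, ImageStim) else len(boxes)
    H, W = pixels.shape[:2]
    weight = np.zeros((H, W))
    for box in boxes:
        box.validate_inside(pixels)
        w_local = soft_ellipse_weight(box.h, box.w, fade_kernel)
        region = weight[box.y:box.y + box.h, box.x:box.x + box.w]
        np.maximum(region, w_local, out=region)
    if variant == "clip":
        out = pixels * weight[..., None]
    elif variant == "noise_clip":
        rng = rng_from(seed)
        out = white_noise(pixels.shape, rng).astype(float) * weight[..., None]
    elif variant == "bbox_cleared":
        out = pixels * (1.0 - weight[..., None])
    else:
        raise ValueError(f"unknown region variant {variant!r}; "
                         "use 'clip', 'noise_clip' or 'bbox_cleared'")
    return ImageStim(pixels=out, item_count=count, boxes=list(boxes), variant=variant,
                     provenance={"seed": int(seed), "fade_kernel": fade_kernel})


def phase_scramble(image: np.ndarray | ImageStim, seed=0, clip: bool = True):
    """Randomize Fourier phases while preserving the amplitude spectrum.

    A random Hermitian-symmetric phase field (the phase of the FFT of a real
    white-noise field, with the DC phase forced to zero so the global mean
    survives) is added to every channel's phase; the inverse transform is
    real up to numerical precision. With ``clip=False`` the float image is
    returned before rounding into [0, 255], which preserves the amplitude
    spectrum to numerical precision.
    """
    pixels = (image.pixels if isinstance(image, ImageStim) else np.asarray(image)).astype(float)
    count = image.item_count if isinstance(image, ImageStim) else 1
    if pixels.ndim == 2:
        pixels = pixels[..., None]
    rng = rng_from(seed)
    field_ = rng.standard_normal(pixels.shape[:2])
    phi = np.angle(np.fft.fft2(field_))
    phi[0, 0] = 0.0  # keep the global mean intact
    out = np.empty_like(pixels)
    for ch in range(pixels.shape[2]):
        F = np.fft.fft2(pixels[..., ch])
        out[..., ch] = np.fft.ifft2(np.abs(F) * np.exp(1j * (np.angle(F) + phi))).real
    out = np.squeeze(out)
    if not clip:
        return out
    return ImageStim(pixels=out, item_count=count, variant="phase_scrambled",
                     provenance={"seed": int(seed)})
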