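"""Synthetic dense small-target scenes ("pest boards") with YOLO labels.

Generates images with the statistical structure of sticky-trap pest
imagery: many small elliptical targets (1-6 % of the image side by
default), frequent overlap/occlusion, a long-tailed class distribution and
a textured background.  Each class has a deterministic colour/shape
signature so that detectors can actually learn to separate classes.  All
sampling is driven by a single seed, so scenes are exactly reproducible.

Also implements the offline augmentations (flips, 90-degree rotation,
brightness, translations) and the online ones (4-image mosaic, pixel-space
mixup with label union), with consistent box transforms throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SceneConfig", "LabelledScene", "generate_scene", "generate_dataset",
           "write_yolo_dataset", "read_yolo_labels", "offline_augment",
           "mosaic", "mixup", "OFFLINE_OPS", "class_palette"]

#: minimum fraction of the original box area that must survive clipping
MIN_BOX_AREA_FRACTION = 0.2

OFFLINE_OPS = ("hflip", "vflip", "rot90", "brightness",
               "translate_x", "translate_y")


def _long_tailed_weights(num_classes: int) -> np.ndarray:
    w = 1.0 / (np.arange(num_classes) + 1.0) ** 1.5
    return w / w.sum()


@dataclass
class SceneConfig:
    """Conditions of the synthetic pest-board scenes.

    Defaults emulate dense small-target trap imagery: objects span 1-6 % of
    the image side, around a third of them are placed overlapping a
    previous one, and class frequencies follow a long-tailed power law.
    """

    image_size: int = 256
    num_classes: int = 24
    objects_per_image: float = 12.0       # Poisson mean
    target_size_range: tuple = (0.01, 0.06)
    occlusion_rate: float = 0.3
    class_frequencies: tuple | None = None
    texture_sigma: float = 6.0            # background correlation length (px)
    texture_amplitude: float = 18.0       # background noise amplitude (0-255)

    def __post_init__(self):
        lo, hi = self.target_size_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("target_size_range must lie within (0, 0.5)")
        if self.class_frequencies is not None:
            f = np.asarray(self.class_frequencies, dtype=float)
            if len(f) != self.num_classes or abs(f.sum() - 1) > 1e-6:
                raise ValueError("class_frequencies must have num_classes entries summing to 1")

    def frequencies(self) -> np.ndarray:
        if self.class_frequencies is not None:
            return np.asarray(self.class_frequencies, dtype=float)
        return _long_tailed_weights(self.num_classes)


@dataclass
class LabelledScene:
    """An RGB image plus (class, (cx, cy, w, h)) annotations in [0, 1]."""

    image: np.ndarray
    annotations: list


def class_palette(num_classes: int) -> np.ndarray:
    """Deterministic, well-separated RGB colour per class (uint8)."""
    hues = (0.13 + 0.61803398875 * np.arange(num_classes)) % 1.0
    sat = 0.55 + 0.35 * ((np.arange(num_classes) * 7) % 3) / 2.0
    val = 0.35 + 0.4 * ((np.arange(num_classes) * 5) % 4) / 3.0
    rgb = np.zeros((num_classes, 3))
    for i, (h, s, v) in enumerate(zip(hues, sat, val)):
        k = int(h * 6) % 6
        f = h * 6 - int(h * 6)
        p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
        rgb[i] = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][k]
    return (rgb * 255).astype(np.uint8)


def _render_blob(canvas, cx, cy, rx, ry, angle, color, rng, wobble):
    """Draw one anti-aliased, slightly irregular ellipse; returns its mask bbox."""
    size = canvas.shape[0]
    pad = int(np.ceil(max(rx, ry))) + 2
    x0, x1 = int(np.floor(cx)) - pad, int(np.floor(cx)) + pad + 1
    y0, y1 = int(np.floor(cy)) - pad, int(np.floor(cy)) + pad + 1
    x0c, x1c = max(x0, 0), min(x1, size)
    y0c, y1c = max(y0, 0), min(y1, size)
    if x0c >= x1c or y0c >= y1c:
        return None
    ss = 3  # supersampling factor for anti-aliasing
    ys = (np.arange(y0c * ss, y1c * ss) + 0.5) / ss - cy
    xs = (np.arange(x0c * ss, x1c * ss) + 0.5) / ss - cx
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx * ca + yy * sa) / rx
    v = (-xx * sa + yy * ca) / ry
    theta = np.arctan2(v, u)
    r_mod = 1.0 + wobble[0] * np.cos(2 * theta + wobble[2]) + wobble[1] * np.cos(3 * theta)
    inside = (u ** 2 + v ** 2) <= r_mod ** 2
    h, w = y1c - y0c, x1c - x0c
    cov = inside.reshape(h, ss, w, ss).mean(axis=(1, 3))
    if cov.max() <= 0:
        return None
    region = canvas[y0c:y1c, x0c:x1c].astype(np.float32)
    shade = 1.0 - 0.25 * ((u ** 2 + v ** 2).reshape(h, ss, w, ss).mean(axis=(1, 3)).clip(0, 1))
    blob_color = color[None, None, :] * shade[..., None]
    canvas[y0c:y1c, x0c:x1c] = (region * (1 - cov[..., None])
                                + blob_color * cov[..., None]).astype(np.uint8)
    mask = cov > 0.25
    if not mask.any():
        return None
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    return (x0c + cols[0], y0c + rows[0], x0c + cols[-1] + 1, y0c + rows[-1] + 1)


def generate_scene(cfg: SceneConfig, seed: int) -> LabelledScene:
    """Render one scene; deterministic for a given (cfg, seed)."""
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    base = np.array([168, 152, 120], dtype=np.float32)  # trap-board beige
    noise = rng.normal(0, 1, (size, size, 3)).astype(np.float32)
    noise = gaussian_filter(noise, sigma=(cfg.texture_sigma, cfg.texture_sigma, 0))
    noise *= cfg.texture_amplitude / max(noise.std(), 1e-6)
    img = np.clip(base[None, None] + noise, 0, 255).astype(np.uint8)

    palette = class_palette(cfg.num_classes).astype(np.float32)
    freqs = cfg.frequencies()
    n_obj = int(rng.poisson(cfg.objects_per_image))
    annotations = []
    placed = []
    lo, hi = cfg.target_size_range
    for _ in range(n_obj):
        cls = int(rng.choice(cfg.num_classes, p=freqs))
        diam = rng.uniform(lo, hi) * size
        aspect = rng.uniform(0.6, 1.6) * (1.0 + 0.2 * ((cls * 3) % 4) / 3.0)
        rx = max(diam / 2 * np.sqrt(aspect), 0.8)
        ry = max(diam / 2 / np.sqrt(aspect), 0.8)
        if placed and rng.uniform() < cfg.occlusion_rate:
            px, py = placed[int(rng.integers(len(placed)))]
            cx = np.clip(px + rng.normal(0, diam * 0.6), 0, size - 1)
            cy = np.clip(py + rng.normal(0, diam * 0.6), 0, size - 1)
        else:
            cx, cy = rng.uniform(0, size), rng.uniform(0, size)
        angle = rng.uniform(0, np.pi)
        color = np.clip(palette[cls] + rng.normal(0, 12, 3), 0, 255)
        wobble = (0.05 + 0.1 * ((cls * 5) % 3) / 2.0, 0.05 * ((cls + 1) % 2),
                  rng.uniform(0, 2 * np.pi))
        bbox = _render_blob(img, cx, cy, rx, ry, angle, color, rng, wobble)
        if bbox is None:
            continue
        bx0, by0, bx1, by1 = bbox
        bw, bh = (bx1 - bx0) / size, (by1 - by0) / size
        if bw <= 0 or bh <= 0:
            continue
        annotations.append((cls, ((bx0 + bx1) / 2 / size, (by0 + by1) / 2 / size, bw, bh)))
        placed.append((cx, cy))
    return LabelledScene(image=img, annotations=annotations)


def generate_dataset(cfg: SceneConfig, n_scenes: int, seed: int) -> list:
    """A list of scenes with per-scene seeds derived from `seed`."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=n_scenes)
    return [generate_scene(cfg, int(s)) for s in seeds]


# ---------------------------------------------------------------------------
# YOLO txt dataset I/O
# ---------------------------------------------------------------------------


def write_yolo_dataset(scenes, out_dir, split_ratios=(0.7, 0.2, 0.1)) -> dict:
    """Write images/ and labels/ trees in YOLO txt format; returns a manifest.

    Splits are deterministic and consecutive (no shuffling): the first 70 %
    of scenes become `train`, then `val`, then `test` for the default 7:2:1.
    """
    from PIL import Image
    if abs(sum(split_ratios) - 1.0) > 1e-6:
        raise ValueError("split ratios must sum to 1")
    out = Path(out_dir)
    names = ("train", "val", "test")[: len(split_ratios)]
    n = len(scenes)
    bounds = np.floor(np.cumsum([0] + list(split_ratios)) * n + 1e-9).astype(int)
    bounds[-1] = n
    manifest = {"splits": {}, "total": n}
    for si, split in enumerate(names):
        img_dir = out / "images" / split
        lbl_dir = out / "labels" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        count = 0
        for i in range(bounds[si], bounds[si + 1]):
            stem = f"scene_{i:05d}"
            Image.fromarray(scenes[i].image).save(img_dir / f"{stem}.png")
            lines = [f"{c} {b[0]:.6f} {b[1]:.6f} {b[2]:.6f} {b[3]:.6f}"
                     for c, b in scenes[i].annotations]
            (lbl_dir / f"{stem}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
            count += 1
        manifest["splits"][split] = count
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_yolo_labels(path) -> list:
    """Parse one YOLO txt label file back to (class, (cx, cy, w, h)) tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        out.append((int(parts[0]), tuple(float(p) for p in parts[1:5])))
    return out


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------


def _clip_box(b, min_area_frac=MIN_BOX_AREA_FRACTION):
    """Clip a normalised box to [0,1]^2; None if too little area survives."""
    cx, cy, w, h = b
    x0, x1 = np.clip(cx - w / 2, 0, 1), np.clip(cx + w / 2, 0, 1)
    y0, y1 = np.clip(cy - h / 2, 0, 1), np.clip(cy + h / 2, 0, 1)
    nw, nh = x1 - x0, y1 - y0
    if nw <= 0 or nh <= 0 or (nw * nh) < min_area_frac * w * h:
        return None
    return ((x0 + x1) / 2, (y0 + y1) / 2, nw, nh)


def offline_augment(scene: LabelledScene, op: str, magnitude: float = 0.2,
                    brightness_factor: float = 1.25) -> LabelledScene:
    """Apply one of the six offline augmentations with consistent boxes.

    ``hflip``/``vflip`` mirror the image; ``rot90`` rotates a quarter turn;
    ``brightness`` scales pixel values (boxes untouched); the translations
    shift by `magnitude` of the image side, dropping boxes with less than
    20 % of their area left in frame.
    """
    if op not in OFFLINE_OPS:
        raise ValueError(f"unknown op '{op}'; choose from {OFFLINE_OPS}")
    img, anns = scene.image, scene.annotations
    if op == "hflip":
        out = img[:, ::-1].copy()
        new = [(c, (1 - b[0], b[1], b[2], b[3])) for c, b in anns]
    elif op == "vflip":
        out = img[::-1].copy()
        new = [(c, (b[0], 1 - b[1], b[2], b[3])) for c, b in anns]
    elif op == "rot90":
        # image[y][x] -> image'[x][H-1-y]: (cx, cy) -> (1-cy, cx), w/h swap
        out = np.rot90(img, k=-1).copy()
        new = [(c, (1 - b[1], b[0], b[3], b[2])) for c, b in anns]
    elif op == "brightness":
        out = np.clip(img.astype(np.float32) * brightness_factor, 0, 255).astype(np.uint8)
        new = list(anns)
    else:
        size = img.shape[0]
        shift = int(round(magnitude * size))
        fill = np.median(img.reshape(-1, 3), axis=0).astype(np.uint8)
        out = np.full_like(img, fill[None, None])
        if op == "translate_x":
            if shift >= 0:
                out[:, shift:] = img[:, : size - shift]
            else:
                out[:, :shift] = img[:, -shift:]
            moved = [(c, (b[0] + shift / size, b[1], b[2], b[3])) for c, b in anns]
        else:
            if shift >= 0:
                out[shift:] = img[: size - shift]
            else:
                out[:shift] = img[-shift:]
            moved = [(c, (b[0], b[1] + shift / size, b[2], b[3])) for c, b in anns]
        new = []
        for c, b in moved:
            clipped = _clip_box(b)
            if clipped is not None:
                new.append((c, clipped))
        return LabelledScene(out, new)
    return LabelledScene(out, new)


def augment_rare_classes(scenes, rare_classes, ops=OFFLINE_OPS, seed: int = 0):
    """Offline augmentation targeted at under-represented classes.

    Every scene containing at least one annotation of a class in
    `rare_classes` is expanded with one augmented copy per op in `ops`
    (sampled order fixed by `seed`); scenes without rare classes pass
    through unchanged.  Returns the enlarged scene list.
    """
    rng = np.random.default_rng(seed)
    out = list(scenes)
    rare = set(rare_classes)
    for scene in scenes:
        if not rare.intersection(c for c, _ in scene.annotations):
            continue
        for op in rng.permutation(list(ops)):
            out.append(offline_augment(scene, str(op)))
    return out


def _resize_nearest(img: np.ndarray, h: int, w: int) -> np.ndarray:
    ys = (np.arange(h) * img.shape[0] / h).astype(int)
    xs = (np.arange(w) * img.shape[1] / w).astype(int)
    return img[ys][:, xs]


def mosaic(scenes, seed: int) -> LabelledScene:
    """Tile four scenes into one around a randomised center point."""
    if len(scenes) != 4:
        raise ValueError("mosaic requires exactly four scenes")
    rng = np.random.default_rng(seed)
    size = scenes[0].image.shape[0]
    cx = int(rng.uniform(0.3, 0.7) * size)
    cy = int(rng.uniform(0.3, 0.7) * size)
    out = np.zeros_like(scenes[0].image)
    quads = [(0, 0, cx, cy), (cx, 0, size, cy), (0, cy, cx, size), (cx, cy, size, size)]
    anns = []
    for scene, (x0, y0, x1, y1) in zip(scenes, quads):
        qw, qh = x1 - x0, y1 - y0
        if qw <= 0 or qh <= 0:
            continue
        out[y0:y1, x0:x1] = _resize_nearest(scene.image, qh, qw)
        sx, sy = qw / size, qh / size
        for c, (bx, by, bw, bh) in scene.annotations:
            nb = ((x0 + bx * qw) / size, (y0 + by * qh) / size, bw * sx, bh * sy)
            clipped = _clip_box(nb)
            if clipped is not None:
                anns.append((c, clipped))
    return LabelledScene(out, anns)


def mixup(a: LabelledScene, b: LabelledScene, lam: float) -> LabelledScene:
    """Blend two scenes pixel-wise; annotations are the union of both."""
    if not 0 < lam <= 1:
        raise ValueError("lambda must lie in (0, 1]")
    if a.image.shape != b.image.shape:
        raise ValueError("mixup requires matching image sizes")
    img = np.clip(lam * a.image.astype(np.float32)
                  + (1 - lam) * b.image.astype(np.float32), 0, 255).astype(np.uint8)
    return LabelledScene(img, list(a.annotations) + list(b.annotations))
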