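"""Seeded generator of three procedurally distinct plant-texture classes.

The three motifs mirror the morphological axis that separates a cereal crop
from its weeds in field imagery: ``sorghum`` renders a few thick vertical
stalks, ``grass`` many thin oriented blades, ``broadleaf`` a few large
elliptical lobes.  Foreground greens differ modestly between classes, as leaf
reflectance does in the field, and additive Gaussian pixel noise roughens
every image.  Images are written as JPGs in the per-class Train/Val/Test
layout (7:2:1) so the whole pipeline runs with no download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .data import SPLIT_DIRS, DatasetIndex, index_dataset, preprocess

CLASS_NAMES = ("broadleaf", "grass", "sorghum")  # lexicographic = class-id order
_SPLIT_FRACTIONS = {"train": 0.7, "val": 0.2}  # remainder -> test


@dataclass
class SynthConfig:
    n_per_class: int = 50
    image_size: int = 224
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    # brown-green soil/canopy backdrop with a gentle vertical gradient
    base = np.array([92, 84, 48], dtype=float) + rng.uniform(-8, 8, size=3)
    grad = np.linspace(-10, 10, size)[:, None, None]
    return np.clip(base + grad, 0, 255)


def _draw_sorghum(draw: ImageDraw.ImageDraw, size: int, rng: np.random.Generator) -> None:
    # thick full-height stalks with bright midribs, one per vertical band so
    # every image shows the same strong columnar structure
    n = int(rng.integers(5, 7))
    for i in range(n):
        x = (i + rng.uniform(0.3, 0.7)) / n * size
        w = rng.uniform(0.05, 0.08) * size
        lean = rng.uniform(-0.04, 0.04) * size
        color = (int(rng.uniform(50, 80)), int(rng.uniform(120, 160)), int(rng.uniform(40, 70)))
        draw.polygon(
            [(x - w / 2, size), (x + w / 2, size), (x + w / 2 + lean, 0), (x - w / 2 + lean, 0)],
            fill=color,
        )
        draw.line([(x, size), (x + lean, 0)], fill=(160, 210, 120), width=max(1, int(w / 3)))


def _draw_grass(draw: ImageDraw.ImageDraw, size: int, rng: np.random.Generator) -> None:
    # many bright thin blades fanning upward, stratified across the width
    n = 48
    for i in rng.permutation(n):
        x0 = (i + rng.uniform(0, 1)) / n * size
        y0 = rng.uniform(0.4, 1.0) * size
        angle = np.deg2rad(rng.uniform(-60, 60))
        length = rng.uniform(0.3, 0.6) * size
        x1 = x0 + length * np.sin(angle)
        y1 = y0 - length * np.cos(angle)
        color = (int(rng.uniform(120, 160)), int(rng.uniform(200, 245)), int(rng.uniform(90, 130)))
        draw.line([(x0, y0), (x1, y1)], fill=color, width=max(1, int(0.015 * size)))


def _draw_broadleaf(draw: ImageDraw.ImageDraw, size: int, rng: np.random.Generator) -> None:
    # large dark lobes on a jittered 3x3 grid: a dense, consistent canopy
    for gy in range(3):
        for gx in range(3):
            cx = (gx + 0.5 + rng.uniform(-0.25, 0.25)) / 3 * size
            cy = (gy + 0.5 + rng.uniform(-0.25, 0.25)) / 3 * size
            rx = rng.uniform(0.16, 0.26) * size
            ry = rx * rng.uniform(0.65, 1.0)
            color = (int(rng.uniform(8, 25)), int(rng.uniform(45, 75)), int(rng.uniform(20, 45)))
            draw.ellipse(
                [cx - rx, cy - ry, cx + rx, cy + ry],
                fill=color,
                outline=(8, 45, 25),
                width=max(1, int(0.02 * size)),
            )


_RENDERERS = {
    "sorghum": _draw_sorghum,
    "grass": _draw_grass,
    "broadleaf": _draw_broadleaf,
}


def render_image(class_name: str, size: int, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Render one uint8 RGB sample of the given class."""
    bg = _background(size, rng)
    im = Image.fromarray(bg.astype(np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(im)
    _RENDERERS[class_name](draw, size, rng)
    arr = np.asarray(im, dtype=float)
    if noise_sd > 0:
        arr = arr + rng.normal(0, noise_sd, size=arr.shape)
    return np.clip(arr, 0, 255).astype(np.uint8)


def _split_counts(n: int) -> dict[str, int]:
    n_train = int(round(n * _SPLIT_FRACTIONS["train"]))
    n_val = int(round(n * _SPLIT_FRACTIONS["val"]))
    return {"train": n_train, "val": n_val, "test": n - n_train - n_val}


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> DatasetIndex:
    """Write n_per_class JPGs per class under Train/Val/Test and index them."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    rng = np.random.default_rng(cfg.seed)
    counts = _split_counts(cfg.n_per_class)
    for cname in CLASS_NAMES:
        i = 0
        for split, n_split in counts.items():
            split_dir = out / SPLIT_DIRS[split] / cname
            split_dir.mkdir(parents=True, exist_ok=True)
            for _ in range(n_split):
                arr = render_image(cname, cfg.image_size, cfg.noise_sd, rng)
                Image.fromarray(arr).save(split_dir / f"{cname}_{i:04d}.jpg", quality=95)
                i += 1
    return index_dataset(out)


def separability_check(index: DatasetIndex, seed: int = 0, downsample: int = 8) -> float:
    """Balanced accuracy of a nearest-centroid baseline on the test split.

    Features are the channel-mean of each image area-averaged down to
    ``downsample`` x ``downsample`` cells.  Guards that the generated classes
    are learnable at all before the network is blamed for a failure.
    """
    from sklearn.metrics import balanced_accuracy_score

    counts = np.bincount(index.labels(index.pool_ids()), minlength=index.num_classes)
    if counts.min() < 10:
        raise ValueError(f"need >= 10 images per class, got {counts.tolist()}")
    train_ids = index.split_ids("train")
    test_ids = index.split_ids("test")
    if not train_ids or not test_ids:
        raise ValueError("missing train or test split")

    def features(ids: list[int]) -> np.ndarray:
        feats = []
        for i in ids:
            img = preprocess(index.records[i].path, size=4 * downsample)
            lum = img.mean(axis=2)
            blocks = lum.reshape(downsample, 4, downsample, 4).mean(axis=(1, 3))
            feats.append(blocks.ravel())
        return np.stack(feats)

    Xtr, ytr = features(train_ids), index.labels(train_ids)
    Xte, yte = features(test_ids), index.labels(test_ids)
    centroids = np.stack([Xtr[ytr == c].mean(axis=0) for c in range(index.num_classes)])
    d = ((Xte[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    y_pred = d.argmin(axis=1)
    return float(balanced_accuracy_score(yte, y_pred))
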