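"""Dataset indexing, preprocessing, augmentation and stratified folds.

The on-disk layout mirrors the published crop-weed classification dataset:
``root/{Train,Val,Test}/<class_name>/*.jpg`` with one directory per class.
Class identifiers are assigned by lexicographic class-name order; files are
sorted within each class, so indexing is fully deterministic.

Preprocessing is bilinear resize to the network input size and scaling by
1/255 into [0, 1].  Training-time augmentation draws a 45-degree rotation,
25% zoom, 25% shear, 30% width/height shift, independent horizontal/vertical
flips and a multiplicative brightness factor in [0.2, 0.9].
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")
#: canonical on-disk split directory names
SPLIT_DIRS = {"train": "Train", "val": "Val", "test": "Test"}
IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}
DEFAULT_IMAGE_SIZE = 224


@dataclass(frozen=True)
class Record:
    path: str
    label: int
    split: str


@dataclass
class DatasetIndex:
    """File paths + dense integer labels + split assignment."""

    records: list[Record]
    class_names: list[str]

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def split_ids(self, split: str) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.split == split]

    def pool_ids(self, splits: tuple[str, ...] = ("train", "val")) -> list[int]:
        """Indices of the cross-validation pool (train + val by default)."""
        return [i for i, r in enumerate(self.records) if r.split in splits]

    def labels(self, ids: list[int] | None = None) -> np.ndarray:
        recs = self.records if ids is None else [self.records[i] for i in ids]
        return np.array([r.label for r in recs], dtype=int)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "label", "split"])
            for r in self.records:
                w.writerow([r.path, r.label, r.split])

    @classmethod
    def from_csv(cls, path: str | Path, class_names: list[str]) -> "DatasetIndex":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                records.append(Record(row["path"], int(row["label"]), row["split"]))
        return cls(records=records, class_names=class_names)


@dataclass
class AugmentationConfig:
    """Stated augmentation ranges; all draws are uniform over the range."""

    rotation_deg: float = 45.0
    zoom_frac: float = 0.25
    shear_frac: float = 0.25
    h_flip: bool = True
    v_flip: bool = True
    shift_frac: float = 0.30
    brightness_range: tuple[float, float] = (0.2, 0.9)

    def __post_init__(self) -> None:
        for name in ("zoom_frac", "shear_frac", "shift_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.brightness_range
        if lo > hi:
            raise ValueError("brightness_range must be ordered (low, high)")


def index_dataset(
    root_dir: str | Path, splits: tuple[str, ...] = SPLITS
) -> DatasetIndex:
    """Index a Train/Val/Test per-class directory tree deterministically."""
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")

    split_dirs: dict[str, Path] = {}
    for split in splits:
        candidates = [root / SPLIT_DIRS[split], root / split]
        found = next((c for c in candidates if c.is_dir()), None)
        if found is None:
            raise FileNotFoundError(f"missing split directory for {split!r} under {root}")
        split_dirs[split] = found

    class_names = sorted(
        {d.name for split_dir in split_dirs.values() for d in split_dir.iterdir() if d.is_dir()}
    )
    if len(class_names) < 2:
        raise ValueError(f"need at least 2 class directories under {root}, found {class_names}")
    class_ids = {name: i for i, name in enumerate(class_names)}

    records: list[Record] = []
    seen: set[str] = set()
    for split in splits:
        for cname in class_names:
            cdir = split_dirs[split] / cname
            if not cdir.is_dir():
                continue
            files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
            if not files:
                logger.warning("empty class directory %s", cdir)
            for p in files:
                key = str(p)
                if key in seen:
                    raise ValueError(f"duplicate path {key}")
                seen.add(key)
                records.append(Record(key, class_ids[cname], split))
    return DatasetIndex(records=records, class_names=class_names)


def preprocess(image_file: str | Path, size: int = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Decode, bilinear-resize to ``size``x``size`` and scale by 1/255."""
    with Image.open(image_file) as im:
        if im.mode not in ("RGB",):
            if im.mode in ("L", "I", "I;16", "F"):
                warnings.warn(
                    f"{image_file}: grayscale input replicated to 3 channels", stacklevel=2
                )
            im = im.convert("RGB")
        if im.size != (size, size):
            im = im.resize((size, size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float64) / 255.0
    return arr


def _affine_matrix(theta_deg: float, shear: float, zoom: float) -> np.ndarray:
    """Forward 2x2 map on centred (row, col) coordinates: rotate, shear, zoom."""
    t = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    zm = np.array([[zoom, 0.0], [0.0, zoom]])
    return zm @ sh @ rot


def augment(x: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply one random augmentation draw; shape preserved, values in [0, 1].

    Transform order: flip, rotate, shear, zoom, shift, brightness.  Exposed
    regions are filled with nearest-edge values; interpolation is bilinear.
    """
    x = np.asarray(x, dtype=np.float64)
    h, w = x.shape[:2]

    if cfg.h_flip and rng.random() < 0.5:
        x = x[:, ::-1, :]
    if cfg.v_flip and rng.random() < 0.5:
        x = x[::-1, :, :]

    theta = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    zoom = 1.0 + rng.uniform(-cfg.zoom_frac, cfg.zoom_frac)
    shear = rng.uniform(-cfg.shear_frac, cfg.shear_frac)
    dy = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * h
    dx = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * w
    brightness = rng.uniform(*cfg.brightness_range)

    M = _affine_matrix(theta, shear, zoom)
    if not np.allclose(M, np.eye(2)) or dy or dx:
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        Minv = np.linalg.inv(M)
        # output coordinate p maps to input coordinate Minv @ (p - c - t) + c
        offset2 = center - Minv @ (center + np.array([dy, dx]))
        A = np.eye(3)
        A[:2, :2] = Minv
        offset = np.array([offset2[0], offset2[1], 0.0])
        x = ndimage.affine_transform(x, A, offset=offset, order=1, mode="nearest")

    x = np.clip(x * brightness, 0.0, 1.0)
    return np.ascontiguousarray(x)


def stratified_kfold(
    index: DatasetIndex, k: int = 10, seed: int = 0
) -> list[tuple[list[int], list[int]]]:
    """Stratified k folds over the train+val pool; deterministic under seed.

    Returns (train_ids, val_ids) pairs of indices into ``index.records``.
    """
    pool = index.pool_ids()
    y = index.labels(pool)
    counts = np.bincount(y, minlength=index.num_classes)
    small = [index.class_names[i] for i, c in enumerate(counts) if c < k]
    if small:
        raise ValueError(f"classes {small} have fewer than k={k} members in the train+val pool")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pool_arr = np.asarray(pool)
    return [
        (pool_arr[tr].tolist(), pool_arr[va].tolist())
        for tr, va in skf.split(np.zeros(len(pool)), y)
    ]


@dataclass
class ArrayDataset:
    """Images of one index loaded into memory as a (N, H, W, C) batch."""

    X: np.ndarray
    y: np.ndarray
    index: DatasetIndex = field(repr=False)

    @classmethod
    def load(cls, index: DatasetIndex, size: int = DEFAULT_IMAGE_SIZE) -> "ArrayDataset":
        X = np.stack([preprocess(r.path, size=size) for r in index.records])
        return cls(X=X, y=index.labels(), index=index)
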