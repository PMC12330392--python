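"""Reading patient bags, preprocessing/augmentation, and patient-level splits.

Preprocessing follows the usual ultrasound-CNN recipe: resize every frame to
a square target, optionally apply mild stochastic augmentation (horizontal
flip, contrast jitter, small rotation/scale/translation), then standardize
intensities.  Augmentation draws are made independently per image from a
seeded generator, so a (spec, seed) pair fully determines the output.

Splits are always at the patient (bag) level so no examination contributes
frames to both partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, resize, warp
from sklearn.model_selection import train_test_split

from .errors import ConfigurationError, DataIntegrityError, StratificationError
from .simulate import ImageBag

__all__ = ["PreprocessSpec", "load_bags", "preprocess", "split_by_patient", "hflip"]


@dataclass
class PreprocessSpec:
    """Resize/normalize/augment settings applied uniformly to every frame."""

    target_size: int = 64
    augment: bool = False
    hflip_prob: float = 0.5
    contrast_jitter: float = 0.2
    rotate_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.1
    normalize_mean: float = 0.5
    normalize_sd: float = 0.25

    def __post_init__(self):
        if self.target_size < 8:
            raise ConfigurationError("target_size must be >= 8")
        if not (0.0 <= self.hflip_prob <= 1.0):
            raise ConfigurationError("hflip_prob must be in [0, 1]")
        if self.contrast_jitter < 0:
            raise ConfigurationError("contrast_jitter must be >= 0")
        if self.rotate_deg < 0:
            raise ConfigurationError("rotate_deg must be >= 0")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ConfigurationError("scale_range must satisfy 0 < min <= max")
        if self.translate_frac < 0:
            raise ConfigurationError("translate_frac must be >= 0")
        if self.normalize_sd <= 0:
            raise ConfigurationError("normalize_sd must be > 0")


def load_bags(manifest) -> list[ImageBag]:
    """Read one :class:`ImageBag` per patient from a manifest CSV.

    Image paths are resolved relative to the manifest's directory; images in
    a bag keep their manifest row order.  Conflicting labels within a
    patient raise :class:`DataIntegrityError`.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    table = pd.read_csv(manifest)
    required = {"patient_id", "label", "image_path"}
    if not required.issubset(table.columns):
        raise DataIntegrityError(
            f"manifest must have columns {sorted(required)}, got {list(table.columns)}")
    root = manifest.parent
    bags = []
    for patient_id, rows in table.groupby("patient_id", sort=False):
        labels = set(rows["label"].astype(int))
        if len(labels) != 1:
            raise DataIntegrityError(
                f"patient {patient_id} has conflicting labels {sorted(labels)}")
        images = []
        for rel in rows["image_path"]:
            path = root / rel
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im.convert("L"), dtype=np.float32) / 255.0
            except OSError as exc:
                raise OSError(f"unreadable image file: {path}") from exc
            images.append(arr)
        bags.append(ImageBag(patient_id=str(patient_id), images=images,
                             bag_label=labels.pop()))
    return bags


def hflip(image: np.ndarray) -> np.ndarray:
    """Horizontal flip; applying it twice restores the original image."""
    return np.ascontiguousarray(image[:, ::-1])


def _augment_one(img: np.ndarray, spec: PreprocessSpec, rng: np.random.Generator):
    if rng.random() < spec.hflip_prob:
        img = hflip(img)
    if spec.contrast_jitter > 0:
        factor = rng.uniform(1.0 - spec.contrast_jitter, 1.0 + spec.contrast_jitter)
        mean = img.mean()
        img = np.clip(mean + factor * (img - mean), 0.0, 1.0)
    angle = np.deg2rad(rng.uniform(-spec.rotate_deg, spec.rotate_deg))
    scale = rng.uniform(*spec.scale_range)
    h, w = img.shape
    tx = rng.uniform(-spec.translate_frac, spec.translate_frac) * w
    ty = rng.uniform(-spec.translate_frac, spec.translate_frac) * h
    center = np.array([w / 2, h / 2])
    # rotate+scale about the image center, then translate
    tform = (AffineTransform(translation=-center)
             + AffineTransform(rotation=angle, scale=(scale, scale))
             + AffineTransform(translation=center)
             + AffineTransform(translation=(tx, ty)))
    return warp(img, tform.inverse, mode="edge", preserve_range=True)


def preprocess(bag: ImageBag, spec: PreprocessSpec, rng_seed: int = 0) -> ImageBag:
    """Resize, optionally augment, and standardize every frame of a bag.

    Returns a new bag with float32 images of shape (target, target) holding
    ``(x - normalize_mean) / normalize_sd``; label, instance count and
    simulation metadata are preserved.
    """
    rng = np.random.default_rng(rng_seed)
    out_images = []
    for img in bag.images:
        img = np.asarray(img, dtype=np.float64)
        if img.ndim == 3:  # collapse RGB to luminance
            img = img.mean(axis=2)
        if img.ndim != 2 or img.size == 0:
            raise ValueError(
                f"expected non-empty 2-D images, got shape {img.shape}")
        if spec.augment:
            img = _augment_one(img, spec, rng)
        if img.shape != (spec.target_size, spec.target_size):
            img = resize(img, (spec.target_size, spec.target_size),
                         anti_aliasing=True, preserve_range=True)
        img = (img - spec.normalize_mean) / spec.normalize_sd
        out_images.append(img.astype(np.float32))
    return replace(bag, images=out_images)


def split_by_patient(bags: list[ImageBag], train_frac: float = 0.75,
                     stratify: bool = True, seed: int = 0):
    """Split bags (patients) into train/test partitions without leakage."""
    if not (0.0 < train_frac < 1.0):
        raise ConfigurationError("train_frac must be in (0, 1)")
    if len(bags) < 2:
        raise ConfigurationError("need at least 2 bags to split")
    labels = [bag.bag_label for bag in bags]
    strat = None
    if stratify:
        counts = pd.Series(labels).value_counts()
        if (counts < 2).any():
            raise StratificationError(
                "stratified split requires >= 2 bags per class; "
                f"class counts: {counts.to_dict()}")
        strat = labels
    train, test = train_test_split(bags, train_size=train_frac,
                                   stratify=strat, random_state=seed,
                                   shuffle=True)
    return list(train), list(test)
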