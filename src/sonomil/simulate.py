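"""Synthetic grayscale image bags with multiple-instance structure.

Each *bag* stands in for one patient's ultrasound examination: a variable
number of speckle-noise frames sharing a single binary risk label.  The bag
is positive iff it contains at least one positive instance (the standard MIL
assumption).  Negative instances show a regular, homogeneous, low-contrast
ellipse — the sonographic appearance of a low-risk nodule; positive
instances show an irregular-margin ellipse darker than background by a
configurable contrast, stippled with a few bright punctate spots emulating
microcalcifications.

The generator is deterministic: a dataset-level seed spawns one child seed
per bag, so the same config always yields bit-identical images and any
single bag can be regenerated in isolation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError

__all__ = ["SimConfig", "ImageBag", "generate_dataset", "write_manifest"]

BACKGROUND_MEAN = 0.6  # echogenic parenchyma baseline
NEGATIVE_CONTRAST = 0.1  # fixed mild hypoechogenicity of benign-looking nodules


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the desk-scale regime the package is validated in:
    64 px frames, bags of 4-12 frames (mean ~8 frames per examination),
    balanced classes, half the frames of a positive bag carrying the lesion.
    """

    n_bags: int = 100
    bag_size_range: tuple[int, int] = (4, 12)
    witness_rate: float = 0.5
    image_size: int = 64
    lesion_contrast: float = 0.5
    speckle_sd: float = 0.08
    seed: int = 0
    class_balance: float = 0.5

    def __post_init__(self):
        if int(self.n_bags) < 1:
            raise ConfigurationError("n_bags must be a positive count")
        lo, hi = self.bag_size_range
        if lo < 1 or lo > hi:
            raise ConfigurationError("bag_size_range must satisfy 1 <= min <= max")
        if not (0.0 < self.witness_rate <= 1.0):
            raise ConfigurationError("witness_rate must be in (0, 1]")
        if int(self.image_size) < 8:
            raise ConfigurationError("image_size must be at least 8 pixels")
        if not (0.0 <= self.lesion_contrast <= 1.0):
            raise ConfigurationError("lesion_contrast must be in [0, 1]")
        if self.speckle_sd < 0:
            raise ConfigurationError("speckle_sd must be >= 0")
        if not (0.0 < self.class_balance < 1.0):
            raise ConfigurationError("class_balance must be in (0, 1)")


@dataclass
class ImageBag:
    """One patient: N grayscale frames in [0,1] and a single binary label.

    ``instance_labels`` and ``masks`` are simulation-only ground truth used
    by evaluation oracles (key-instance checks, Grad-CAM localization); they
    are never visible to training.  ``masks[i]`` holds boolean ``lesion``
    and ``spots`` arrays for instance i.
    """

    patient_id: str
    images: list[np.ndarray]
    bag_label: int
    instance_labels: list[int] | None = None
    masks: list[dict[str, np.ndarray]] | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.images) < 1:
            raise ConfigurationError("a bag must contain at least one image")
        if self.instance_labels is not None:
            if len(self.instance_labels) != len(self.images):
                raise ConfigurationError("instance_labels length must match images")
            if self.bag_label == 1 and not any(self.instance_labels):
                raise ConfigurationError(
                    "positive bag must contain at least one positive instance")
            if self.bag_label == 0 and any(self.instance_labels):
                raise ConfigurationError(
                    "negative bag must contain no positive instances")

    def __len__(self) -> int:
        return len(self.images)


def _ellipse_mask(size: int, rng: np.random.Generator, irregular: bool):
    """Boolean lesion mask: smooth ellipse, or radius-modulated if irregular."""
    cy, cx = (size / 2) + rng.uniform(-0.08, 0.08, size=2) * size
    ry = rng.uniform(0.13, 0.22) * size
    rx = rng.uniform(0.13, 0.22) * size
    tilt = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = np.cos(tilt) * dx + np.sin(tilt) * dy
    v = -np.sin(tilt) * dx + np.cos(tilt) * dy
    r = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    if irregular:
        # low-order angular modulation of the margin
        theta = np.arctan2(v / ry, u / rx)
        boundary = np.ones_like(theta)
        for k in range(2, 6):
            boundary += rng.uniform(0.0, 0.15) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        mask = r <= boundary
    else:
        mask = r <= 1.0
    return mask


def _render_instance(rng: np.random.Generator, size: int, positive: bool,
                     lesion_contrast: float, speckle_sd: float):
    img = np.full((size, size), BACKGROUND_MEAN, dtype=np.float64)
    lesion = _ellipse_mask(size, rng, irregular=positive)
    contrast = lesion_contrast if positive else NEGATIVE_CONTRAST
    img[lesion] -= contrast
    spots = np.zeros((size, size), dtype=bool)
    if positive:
        ys, xs = np.nonzero(lesion)
        n_spots = int(rng.integers(3, 9))
        for _ in range(n_spots):
            j = int(rng.integers(len(ys)))
            radius = int(rng.integers(1, 3))  # 1-2 px punctate spots
            y0, x0 = ys[j], xs[j]
            yy, xx = np.mgrid[max(0, y0 - radius):min(size, y0 + radius + 1),
                              max(0, x0 - radius):min(size, x0 + radius + 1)]
            spot = (yy - y0) ** 2 + (xx - x0) ** 2 < radius**2 + 1
            spots[yy[spot], xx[spot]] = True
        img[spots] = 0.98  # bright microcalcification-like foci
    if speckle_sd > 0:
        img += rng.normal(0.0, speckle_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return img.astype(np.float32), lesion, spots


def bag_seed_sequences(config: SimConfig):
    """Dataset-level child seeds: entry 0 drives label assignment, entry i+1 bag i."""
    return np.random.SeedSequence(config.seed).spawn(config.n_bags + 1)


def draw_bag_size(rng: np.random.Generator, config: SimConfig) -> int:
    """First draw from a bag's RNG stream; exposed so callers can replay it."""
    lo, hi = config.bag_size_range
    return int(rng.integers(lo, hi + 1))


def generate_dataset(config: SimConfig) -> list[ImageBag]:
    """Generate ``config.n_bags`` bags; round(n_bags * class_balance) are positive.

    Within a positive bag of size N, exactly ``max(1, round(witness_rate*N))``
    instances are positive; negative bags contain no positive instances.
    """
    children = bag_seed_sequences(config)
    label_rng = np.random.default_rng(children[0])
    n_pos = int(round(config.n_bags * config.class_balance))
    labels = np.zeros(config.n_bags, dtype=int)
    labels[:n_pos] = 1
    label_rng.shuffle(labels)

    bags = []
    for i in range(config.n_bags):
        rng = np.random.default_rng(children[i + 1])
        n = draw_bag_size(rng, config)
        inst_labels = [0] * n
        if labels[i] == 1:
            k = max(1, int(round(config.witness_rate * n)))
            for j in rng.choice(n, size=min(k, n), replace=False):
                inst_labels[int(j)] = 1
        images, masks = [], []
        for j in range(n):
            img, lesion, spots = _render_instance(
                rng, config.image_size, bool(inst_labels[j]),
                config.lesion_contrast, config.speckle_sd)
            images.append(img)
            masks.append({"lesion": lesion, "spots": spots})
        bags.append(ImageBag(
            patient_id=f"P{i:04d}",
            images=images,
            bag_label=int(labels[i]),
            instance_labels=inst_labels,
            masks=masks,
        ))
    return bags


def write_manifest(bags: list[ImageBag], out_dir) -> Path:
    """Save bags as 8-bit PNGs under per-patient directories plus a manifest CSV.

    The manifest has one row per image with columns
    ``patient_id,label,image_path`` (paths relative to the manifest's
    directory); all rows of one patient share the bag label.
    """
    if not bags:
        raise ValueError("cannot write a manifest for an empty bag list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "image_path"])
        for bag in bags:
            patient_dir = out_dir / bag.patient_id
            patient_dir.mkdir(exist_ok=True)
            for j, img in enumerate(bag.images):
                rel = Path(bag.patient_id) / f"img_{j:03d}.png"
                arr = np.clip(np.round(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(out_dir / rel)
                writer.writerow([bag.patient_id, bag.bag_label, rel.as_posix()])
    return manifest_path
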