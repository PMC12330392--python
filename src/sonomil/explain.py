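"""Interpretability: per-instance Grad-CAM saliency and bag attention reports.

Two distinct notions of "where the model looked" are kept separate:

* **Grad-CAM** is spatial, per frame: channel weights are the spatial mean
  of d(bag logit)/d(activation) at the deepest convolutional layer, and the
  heatmap is the ReLU of the weight-summed activation maps, max-normalized
  per frame and bilinearly upsampled to the frame size.
* **Attention weights** are per instance: the softmax importances the MIL
  pooling assigned to each frame of the bag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize

from .errors import CapabilityError
from .model import BagPrediction, MILModel, _stack_bag

__all__ = ["Heatmap", "AttentionReport", "grad_cam", "attention_report",
           "render_overlay"]


@dataclass
class Heatmap:
    """Nonnegative saliency map in [0,1] at the instance image's resolution."""

    values: np.ndarray
    instance_index: int
    target: float  # the bag logit the gradients were taken from
    flat: bool = False  # True when every activation was gated off (all-zero map)


@dataclass
class AttentionReport:
    """Instances ranked by attention weight (ties broken by instance index)."""

    entries: list[dict] = field(default_factory=list)
    key_instances: list[int] = field(default_factory=list)


def grad_cam(model: MILModel, bag, instance_index: int) -> Heatmap:
    """Grad-CAM heatmap for one instance of a (preprocessed) bag.

    An all-zero map (every weighted activation gated off by the ReLU) is
    returned with ``flat=True`` rather than raised.
    """
    images = _stack_bag(bag)
    n = images.shape[0]
    if not (0 <= instance_index < n):
        raise IndexError(f"instance_index {instance_index} out of range for bag of {n}")
    out = model.forward(images)
    out["logit"].backward()
    act = out["activation"]  # (N, D, h, w)
    grads = act.grad
    model.zero_grad()
    if grads is None:
        grads = np.zeros_like(act.data)
    weights = grads[instance_index].mean(axis=(1, 2))            # (D,)
    cam = np.maximum(np.tensordot(weights, act.data[instance_index], axes=1), 0.0)
    peak = float(cam.max())
    flat = peak <= 0.0
    if not flat:
        cam = cam / peak
    target_shape = images.shape[2:]
    if cam.shape != target_shape:
        cam = resize(cam, target_shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        cam = np.clip(cam, 0.0, 1.0)
    return Heatmap(values=cam.astype(np.float64),
                   instance_index=instance_index,
                   target=float(out["logit"].data), flat=flat)


def attention_report(prediction: BagPrediction, top_k: int = 3) -> AttentionReport:
    """Rank a bag's instances by attention weight, descending."""
    if prediction.attention is None:
        raise CapabilityError(
            "attention report requires a prediction made with attention pooling")
    weights = prediction.attention.a
    # descending weight, ascending index on ties
    order = np.lexsort((np.arange(weights.size), -weights))
    entries = [{"index": int(idx), "weight": float(weights[idx]), "rank": rank + 1}
               for rank, idx in enumerate(order)]
    key = [int(i) for i in order[:max(0, top_k)]]
    return AttentionReport(entries=entries, key_instances=key)


def render_overlay(image: np.ndarray, heatmap: Heatmap, out_path,
                   alpha: float = 0.6, cmap: str = "jet") -> Path:
    """Warm-colormap alpha blend of a heatmap over a grayscale frame, saved as PNG.

    Blend weight scales with local heat, so zero-heat regions show the
    untouched grayscale image.  Purely a visualization; no numeric claims.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape != heatmap.values.shape:
        raise ValueError(
            f"image shape {image.shape} must match heatmap shape {heatmap.values.shape}")
    lo, hi = image.min(), image.max()
    gray = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    rgb_gray = np.stack([gray] * 3, axis=-1)
    rgb_heat = colormaps[cmap](heatmap.values)[..., :3]
    blend = alpha * heatmap.values[..., None]
    rgb = (1.0 - blend) * rgb_gray + blend * rgb_heat
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)).save(out_path)
    return out_path
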