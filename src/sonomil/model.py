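"""The MIL network: instance encoder -> attention aggregation -> bag probability.

A bag of N frames is encoded to an instance feature matrix H in R^{N x 512}
(one spatially pooled deep-convolution feature per frame).  Aggregation to a
single bag feature M follows the attention-based MIL (AB-MIL) construction:

    s_i = W2^T tanh(W1^T h_i + b1) + b2          (scores, W1: 512x128, W2: 128x1)
    a_i = exp(s_i) / sum_j exp(s_j)              (softmax over the bag)
    M   = sum_i a_i h_i

with element-wise max and mean pooling available as ablation baselines.  The
bag probability is a sigmoid of a linear map of M.  Because the softmax and
the weighted sum are symmetric in instance order, the bag probability is
invariant to permutations of the frames; b2 is a scalar score offset and
cancels inside the softmax.

Two routes expose the same math: differentiable :class:`Module` components
used in training, and plain-NumPy functional forms (:func:`attention_pool`,
:func:`max_pool`, :func:`mean_pool`, :func:`classify_bag`) operating on
explicit parameter structs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .errors import CapabilityError, ConfigurationError, EmptyBagError
from .nn import (Conv2d, Linear, Module, global_avg_pool,
                 global_max_pool, max_pool2x2, softmax)
from .simulate import ImageBag

__all__ = [
    "EncoderSpec", "AttentionParams", "AttentionWeights", "BagPrediction",
    "TinyCNNEncoder", "AttentionPooling", "MILModel", "build_encoder",
    "encode_instances", "attention_pool", "max_pool", "mean_pool",
    "classify_bag", "save_checkpoint", "load_checkpoint",
]

FEATURE_DIM = 512


@dataclass
class EncoderSpec:
    """Instance-encoder selection.

    ``tinycnn`` is a compact from-scratch CNN that runs on CPU; ``vgg13``
    denotes an ImageNet-pretrained VGG13 backbone, which needs pretrained
    weights and a deep-learning runtime and is therefore reported as an
    unavailable capability when requested.
    """

    backbone: str = "tinycnn"
    pretrained: bool = False
    feature_dim: int = FEATURE_DIM
    pool: str = "max"  # spatial pooling of the deepest feature map

    def __post_init__(self):
        if self.backbone not in ("tinycnn", "vgg13"):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")
        if self.pool not in ("avg", "max"):
            raise ConfigurationError(f"spatial pool must be 'avg' or 'max', got {self.pool!r}")
        if self.feature_dim < 1:
            raise ConfigurationError("feature_dim must be positive")
        if self.backbone == "tinycnn" and self.pretrained:
            raise ConfigurationError("pretrained weights exist only for backbone='vgg13'")


@dataclass
class AttentionParams:
    """Explicit attention parameters: W1 (D x 128), b1 (128,), W2 (128 x 1), b2 scalar."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float

    def __post_init__(self):
        self.W1 = np.asarray(self.W1)
        self.b1 = np.asarray(self.b1)
        self.W2 = np.asarray(self.W2)
        if self.W1.ndim != 2 or self.W2.shape != (self.W1.shape[1], 1):
            raise ConfigurationError(
                f"inconsistent attention shapes W1 {self.W1.shape}, W2 {self.W2.shape}")
        if self.b1.shape != (self.W1.shape[1],):
            raise ConfigurationError(f"b1 must have shape ({self.W1.shape[1]},)")


@dataclass
class AttentionWeights:
    """Softmax-normalized instance importances: a_i > 0, sum a_i = 1."""

    a: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.ndim != 1 or self.a.size < 1:
            raise EmptyBagError("attention weights must be a non-empty vector")
        if not np.all(np.isfinite(self.a)) or np.any(self.a <= 0):
            raise ValueError("attention weights must be finite and positive")
        if abs(self.a.sum() - 1.0) > 1e-6:
            raise ValueError(f"attention weights must sum to 1, got {self.a.sum()}")

    def __len__(self):
        return self.a.size


@dataclass
class BagPrediction:
    """Bag-level risk output: probability = sigmoid(logits)."""

    probability: float
    logits: float
    attention: AttentionWeights | None
    pooled_feature: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

class TinyCNNEncoder(Module):
    """Three 3x3 conv/pool blocks plus a 1x1 projection to ``feature_dim`` channels.

    The deepest (projection) feature map is spatially pooled to one vector
    per instance, so the output is N x feature_dim at any input resolution
    whose side is divisible by 8.  Spatial max pooling is the default: it
    routes gradients to the activating location, which keeps Grad-CAM
    saliency anchored to the image evidence; average pooling is available
    but diffuses saliency over the frame (see docs/methods.md).
    """

    def __init__(self, rng: np.random.Generator, feature_dim: int = FEATURE_DIM,
                 spatial_pool: str = "max"):
        self.conv1 = Conv2d(1, 8, 3, rng, stride=2)  # stride-2 stem halves resolution
        self.conv2 = Conv2d(8, 16, 3, rng)
        self.conv3 = Conv2d(16, 32, 3, rng)
        self.proj = Conv2d(32, feature_dim, 1, rng, padding=0)
        self.spatial_pool = spatial_pool
        self.feature_dim = feature_dim

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (features (N, D), deepest activation map (N, D, h, w))."""
        h = self.conv1(x).relu()
        h = max_pool2x2(self.conv2(h).relu())
        h = max_pool2x2(self.conv3(h).relu())
        act = self.proj(h).relu()
        pool = global_avg_pool if self.spatial_pool == "avg" else global_max_pool
        return pool(act), act

    __call__ = forward


def build_encoder(spec: EncoderSpec, rng: np.random.Generator) -> TinyCNNEncoder:
    if spec.backbone == "vgg13":
        raise CapabilityError(
            "backbone 'vgg13' requires ImageNet-pretrained weights and a deep "
            "learning runtime that are not available here; use backbone='tinycnn'")
    return TinyCNNEncoder(rng, feature_dim=spec.feature_dim, spatial_pool=spec.pool)


def _stack_bag(bag) -> np.ndarray:
    if isinstance(bag, ImageBag):
        images = bag.images
    else:
        images = list(bag)
    if len(images) == 0:
        raise EmptyBagError("cannot encode an empty bag")
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    if arr.ndim != 3:
        raise ValueError(f"expected N equally-sized 2-D images, got shape {arr.shape}")
    return arr[:, None, :, :]  # (N, 1, H, W)


def encode_instances(bag, encoder: TinyCNNEncoder | None = None,
                     spec: EncoderSpec | None = None,
                     seed: int = 0) -> np.ndarray:
    """Encode a (preprocessed) bag to an instance feature matrix H (N x D)."""
    if encoder is None:
        encoder = build_encoder(spec or EncoderSpec(), np.random.default_rng(seed))
    feats, _ = encoder(Tensor(_stack_bag(bag)))
    return np.asarray(feats.data, dtype=np.float64)


# ---------------------------------------------------------------------------
# Pooling operators (functional, NumPy)
# ---------------------------------------------------------------------------

def attention_pool(H: np.ndarray, params: AttentionParams):
    """AB-MIL aggregation: returns (AttentionWeights, M) for H (N x D).

    Scores use a max-subtracted softmax for numerical stability; the result
    is exact because softmax is shift-invariant.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise EmptyBagError(f"H must be a non-empty N x D matrix, got shape {H.shape}")
    if not np.all(np.isfinite(H)):
        raise ValueError("instance features must be finite")
    scores = np.tanh(H @ params.W1 + params.b1) @ params.W2[:, 0] + params.b2
    shifted = scores - scores.max()
    e = np.exp(shifted)
    a = e / e.sum()
    M = a @ H
    return AttentionWeights(a=a), M


def max_pool(H: np.ndarray) -> np.ndarray:
    """Element-wise maximum over instances: (N x D) -> (D,)."""
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[0] < 1:
        raise EmptyBagError(f"H must be a non-empty N x D matrix, got shape {H.shape}")
    return H.max(axis=0)


def mean_pool(H: np.ndarray) -> np.ndarray:
    """Arithmetic mean over instances: (N x D) -> (D,)."""
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[0] < 1:
        raise EmptyBagError(f"H must be a non-empty N x D matrix, got shape {H.shape}")
    return H.mean(axis=0)


def _sigmoid(z: float) -> float:
    z = float(z)
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    return np.exp(z) / (1.0 + np.exp(z))


def classify_bag(M: np.ndarray, weight: np.ndarray, bias: float,
                 attention: AttentionWeights | None = None) -> BagPrediction:
    """Linear head + sigmoid on the pooled bag feature M."""
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ValueError("pooled feature must be finite")
    logits = float(M @ np.asarray(weight, dtype=np.float64).reshape(-1) + bias)
    return BagPrediction(probability=_sigmoid(logits), logits=logits,
                         attention=attention, pooled_feature=M)


# ---------------------------------------------------------------------------
# Differentiable modules
# ---------------------------------------------------------------------------

class AttentionPooling(Module):
    """Differentiable AB-MIL attention: two-layer tanh scorer + softmax."""

    def __init__(self, feature_dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(feature_dim, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)

    def forward(self, H: Tensor) -> tuple[Tensor, Tensor]:
        scores = self.fc2(self.fc1(H).tanh()).reshape(-1)  # (N,)
        a = softmax(scores, axis=0)
        M = a @ H
        return a, M

    __call__ = forward

    def params(self) -> AttentionParams:
        return AttentionParams(W1=self.fc1.W.data.copy(), b1=self.fc1.b.data.copy(),
                               W2=self.fc2.W.data.copy(), b2=float(self.fc2.b.data[0]))


class MILModel(Module):
    """encoder -> instance features -> pooling -> linear head -> bag probability."""

    POOLINGS = ("attention", "max", "mean")

    def __init__(self, encoder_spec: EncoderSpec | None = None,
                 pooling: str = "attention", attn_hidden: int = 128, seed: int = 0):
        if pooling not in self.POOLINGS:
            raise ConfigurationError(
                f"pooling must be one of {self.POOLINGS}, got {pooling!r}")
        spec = encoder_spec or EncoderSpec()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.pooling = pooling
        self.attn_hidden = attn_hidden
        self.seed = seed
        self.encoder = build_encoder(spec, rng)
        self.attention = (AttentionPooling(spec.feature_dim, attn_hidden, rng)
                          if pooling == "attention" else None)
        self.head = Linear(spec.feature_dim, 1, rng)

    # -- forward -------------------------------------------------------------

    def forward(self, images: np.ndarray) -> dict:
        """Full differentiable pass on a stacked bag (N, 1, H, W).

        Returns tensors: ``logit`` (scalar), ``prob``, ``features`` (N, D),
        ``attention`` (N,) or None, ``pooled`` (D,), ``activation``
        (N, D, h, w) — the deepest conv map, read by Grad-CAM.
        """
        x = Tensor(np.asarray(images, dtype=np.float32))
        feats, act = self.encoder(x)
        attn = None
        if self.pooling == "attention":
            attn, pooled = self.attention(feats)
        elif self.pooling == "mean":
            pooled = feats.mean(axis=0)
        else:
            pooled = feats.max(axis=0)
        logit = self.head(pooled).reshape(())
        return {"logit": logit, "prob": logit.sigmoid(), "features": feats,
                "attention": attn, "pooled": pooled, "activation": act}

    __call__ = forward

    def predict(self, bag) -> BagPrediction:
        """Deterministic inference on a preprocessed bag (or list of 2-D arrays)."""
        out = self.forward(_stack_bag(bag))
        attn = (AttentionWeights(a=np.asarray(out["attention"].data, dtype=np.float64))
                if out["attention"] is not None else None)
        return BagPrediction(
            probability=float(out["prob"].data),
            logits=float(out["logit"].data),
            attention=attn,
            pooled_feature=np.asarray(out["pooled"].data, dtype=np.float64),
        )

    # -- introspection / persistence ------------------------------------------

    def config(self) -> dict:
        return {"encoder_spec": asdict(self.spec), "pooling": self.pooling,
                "attn_hidden": self.attn_hidden, "seed": self.seed}


def save_checkpoint(model: MILModel, path, extra: dict | None = None) -> Path:
    """Serialize parameters plus a JSON config fingerprint to a single .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": model.config(), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)
    return path


def load_checkpoint(path) -> tuple[MILModel, dict]:
    """Rebuild a model from :func:`save_checkpoint` output; returns (model, extra)."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg = meta["config"]
    model = MILModel(encoder_spec=EncoderSpec(**cfg["encoder_spec"]),
                     pooling=cfg["pooling"], attn_hidden=cfg["attn_hidden"],
                     seed=cfg["seed"])
    model.load_state_dict(state)
    return model, meta.get("extra", {})
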