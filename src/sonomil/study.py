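"""A reusable driver for the package's synthetic validation study.

One call generates a bag dataset, splits it by patient (train/val/test),
trains a MIL model, and evaluates it — the workflow the examples, the test
suite and the reproduction script all share.  Default study conditions:
250 bags of 64 px frames split 200 (train+val) / 50 (test), witness rate
0.5, lesion contrast 0.5, attention pooling, 20 epochs of Adam at 1e-3
(a from-scratch rate; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eval import auc_score, predict_bags
from .io import PreprocessSpec, preprocess, split_by_patient
from .model import EncoderSpec, MILModel
from .simulate import ImageBag, SimConfig, generate_dataset
from .train import TrainConfig, TrainResult, train

__all__ = ["StudyResult", "run_synthetic_study", "key_instance_hit_rate",
           "gradcam_localization_rate"]


@dataclass
class StudyResult:
    model: MILModel
    train_bags: list[ImageBag]
    val_bags: list[ImageBag]
    test_bags: list[ImageBag]
    predictions: pd.DataFrame
    test_auc: float
    train_result: TrainResult = field(repr=False)


def run_synthetic_study(seed: int = 1, n_bags: int = 250, test_frac: float = 0.2,
                        witness_rate: float = 0.5, lesion_contrast: float = 0.5,
                        image_size: int = 64, bag_size_range=(4, 12),
                        pooling: str = "attention", epochs: int = 20,
                        lr: float = 1e-3, val_frac: float = 0.15,
                        encoder_spec: EncoderSpec | None = None) -> StudyResult:
    """Simulate, split by patient, train, and evaluate one MIL model."""
    config = SimConfig(n_bags=n_bags, bag_size_range=bag_size_range,
                       witness_rate=witness_rate, image_size=image_size,
                       lesion_contrast=lesion_contrast, seed=seed)
    spec = PreprocessSpec(target_size=image_size)
    bags = [preprocess(b, spec, rng_seed=0) for b in generate_dataset(config)]
    trainval, test = split_by_patient(bags, train_frac=1.0 - test_frac,
                                      stratify=True, seed=seed)
    train_bags, val_bags = split_by_patient(trainval, train_frac=1.0 - val_frac,
                                            stratify=True, seed=seed)
    model = MILModel(encoder_spec=encoder_spec, pooling=pooling, seed=seed)
    result = train(train_bags, val_bags, model,
                   TrainConfig(lr=lr, epochs=epochs, seed=seed))
    preds = predict_bags(model, test)
    auc = auc_score(preds["label"].to_numpy(), preds["probability"].to_numpy())
    return StudyResult(model=model, train_bags=train_bags, val_bags=val_bags,
                       test_bags=test, predictions=preds, test_auc=auc,
                       train_result=result)


def key_instance_hit_rate(model: MILModel, bags) -> tuple[int, int]:
    """(hits, total): how often the top-attention instance of a positive bag
    is a truly positive instance per the simulator's ground truth."""
    hits = total = 0
    for bag in bags:
        if bag.bag_label != 1 or bag.instance_labels is None:
            continue
        prediction = model.predict(bag)
        top = int(np.argmax(prediction.attention.a))
        hits += int(bag.instance_labels[top])
        total += 1
    return hits, total


def gradcam_localization_rate(model: MILModel, bags) -> tuple[int, int]:
    """(hits, total): positive test instances whose mean Grad-CAM heat inside
    the simulator's lesion mask exceeds the mean outside."""
    from .explain import grad_cam  # local import to avoid a cycle

    hits = total = 0
    for bag in bags:
        if bag.bag_label != 1 or bag.masks is None:
            continue
        for j, lab in enumerate(bag.instance_labels):
            if not lab:
                continue
            heat = grad_cam(model, bag, j).values
            mask = bag.masks[j]["lesion"] | bag.masks[j]["spots"]
            hits += int(heat[mask].mean() > heat[~mask].mean())
            total += 1
    return hits, total
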