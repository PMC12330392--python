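"""Shared fixtures: small synthetic datasets and session-scoped trained models.

The expensive fixtures (trained studies, the pooling ablation) are built
once per session and shared by every test that needs a trained model, so
the suite trains each configuration exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import sonomil as sm
from sonomil.study import run_synthetic_study

STUDY_SEEDS = (1, 2, 3)
ABLATION_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def small_dataset():
    """40 small bags (32 px) with ground-truth masks, preprocessed."""
    bags = sm.generate_dataset(sm.SimConfig(n_bags=40, image_size=32, seed=11))
    spec = sm.PreprocessSpec(target_size=32)
    return [sm.preprocess(b, spec, rng_seed=0) for b in bags]


@pytest.fixture(scope="session")
def tiny_trained(small_dataset):
    """A quickly trained small model for tests that need non-random weights."""
    trainval, test = sm.split_by_patient(small_dataset, 0.75, True, seed=3)
    tr, val = sm.split_by_patient(trainval, 0.85, True, seed=3)
    model = sm.MILModel(seed=3)
    sm.train(tr, val, model, sm.TrainConfig(lr=1e-3, epochs=6, seed=3))
    return {"model": model, "train": tr, "val": val, "test": test}


@pytest.fixture(scope="session")
def trained_studies():
    """The main synthetic validation study at full scale, one run per seed:
    250 bags (200 train+val / 50 test), 64 px, witness rate 0.5, lesion
    contrast 0.5, attention pooling, 20 epochs."""
    return {seed: run_synthetic_study(seed=seed) for seed in STUDY_SEEDS}


@pytest.fixture(scope="session")
def low_witness_ablation():
    """Attention vs mean pooling in a low-witness-rate regime (0.25), five
    seeds, smaller bags/epochs to keep the comparison desk-scale."""
    results = {"attention": [], "mean": []}
    for seed in ABLATION_SEEDS:
        for pooling in results:
            study = run_synthetic_study(
                seed=seed, n_bags=150, witness_rate=0.25, lesion_contrast=0.3,
                bag_size_range=(6, 12), epochs=12, pooling=pooling)
            results[pooling].append(study.test_auc)
    return {k: np.asarray(v) for k, v in results.items()}
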