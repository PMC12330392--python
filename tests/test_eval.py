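"""Metrics, ROC/AUC, bootstrap CIs and paired model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sonomil as sm
from sonomil.errors import ConfigurationError
from sonomil.eval import bootstrap_metric_samples, roc_points


def frame(labels, probs):
    return pd.DataFrame({"patient_id": [f"p{i}" for i in range(len(labels))],
                         "label": labels, "probability": probs})


def brute_force_metrics(labels, probs, threshold):
    """Confusion-matrix oracle by explicit enumeration."""
    tp = fp = fn = tn = 0
    for y, p in zip(labels, probs):
        pred = 1 if p >= threshold else 0
        if pred and y: tp += 1
        elif pred and not y: fp += 1
        elif not pred and y: fn += 1
        else: tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"accuracy": (tp + tn) / len(labels), "precision": precision,
            "recall": recall, "f1": f1}


def pairwise_auc(labels, probs):
    """O(n^2) Mann-Whitney count with ties at 1/2."""
    wins = pairs = 0.0
    for yi, pi in zip(labels, probs):
        if yi != 1: continue
        for yj, pj in zip(labels, probs):
            if yj != 0: continue
            pairs += 1
            wins += 1.0 if pi > pj else (0.5 if pi == pj else 0.0)
    return wins / pairs


def test_six_patient_hand_table_matches_enumeration_oracle():
    labels = [1, 1, 1, 0, 0, 0]
    probs = [0.9, 0.6, 0.4, 0.7, 0.3, 0.1]
    report = sm.compute_metrics(frame(labels, probs), threshold=0.5, n_boot=100, seed=0)
    oracle = brute_force_metrics(labels, probs, 0.5)
    # TP=2 FP=1 FN=1 TN=2 by hand
    assert oracle == {"accuracy": 4 / 6, "precision": 2 / 3, "recall": 2 / 3, "f1": 2 / 3}
    for name, value in oracle.items():
        assert getattr(report, name).point == pytest.approx(value)
    assert report.auc.point == pytest.approx(pairwise_auc(labels, probs))


def test_perfect_and_constant_classifiers():
    labels = [1, 0, 1, 0]
    report = sm.compute_metrics(frame(labels, labels), n_boot=50, seed=0)
    for name in ("accuracy", "precision", "recall", "f1", "auc"):
        assert getattr(report, name).point == 1.0
    const = sm.compute_metrics(frame(labels, [0.5] * 4), n_boot=50, seed=0)
    assert const.recall.point == 1.0  # ties at the threshold count as positive
    assert const.accuracy.point == 0.5
    assert const.auc.point == 0.5


def test_metric_error_cases():
    with pytest.raises(ValueError):
        sm.compute_metrics(frame([1, 1], [0.2, 0.9]))
    report = sm.compute_metrics(frame([1, 0, 1, 0], [0.1, 0.2, 0.3, 0.0]),
                                threshold=0.9, n_boot=50)
    assert report.precision.point == 0.0
    assert "no_predicted_positives" in report.flags
    with pytest.raises(ConfigurationError):
        sm.compute_metrics(frame([1, 0], [1.2, 0.5]))


def test_trapezoid_auc_equals_pairwise_count_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = int(rng.integers(6, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        probs = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        preds = frame(labels, probs)
        _, _, auc_trap = roc_points(preds)
        assert auc_trap == pytest.approx(pairwise_auc(labels, probs), abs=1e-12)
        assert sm.auc_score(labels, probs) == pytest.approx(auc_trap, abs=1e-12)


def test_roc_curve_is_monotone_from_origin_to_one():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 2, size=30); labels[0], labels[1] = 0, 1
    fpr, tpr, _ = roc_points(frame(labels, rng.uniform(size=30)))
    assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
    assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
    # reversed scores give AUC 0 on separable data
    sep_labels = [0] * 5 + [1] * 5
    sep_probs = [0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3, 0.2, 0.1, 0.0]
    assert sm.auc_score(np.array(sep_labels), np.array(sep_probs)) == 0.0


def test_f1_lies_between_precision_and_recall():
    rng = np.random.default_rng(5)
    for _ in range(40):
        n = int(rng.integers(8, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        report = sm.compute_metrics(frame(labels, rng.uniform(size=n)), n_boot=10)
        p, r, f1 = report.precision.point, report.recall.point, report.f1.point
        if p > 0 and r > 0:
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


def test_paired_comparison_identical_samples_is_degenerate_zero_effect():
    a = np.array([0.8, 0.82, 0.85, 0.9])
    result = sm.paired_comparison(a, a.copy())
    assert result.cohens_d == 0.0
    assert result.effect_band == "negligible"
    assert result.degenerate


def test_paired_comparison_matches_textbook_formulas():
    rng = np.random.default_rng(6)
    n = 40
    b = rng.normal(size=n)
    diff = 0.3 + rng.normal(scale=0.5, size=n)
    a = b + diff
    result = sm.paired_comparison(a, b)
    d_expected = diff.mean() / diff.std(ddof=1)
    t_expected = d_expected * np.sqrt(n)
    p_expected = 2 * stats.t.sf(abs(t_expected), n - 1)
    assert result.cohens_d == pytest.approx(d_expected, abs=1e-12)
    assert result.p_value == pytest.approx(p_expected, rel=1e-9)


@pytest.mark.parametrize("d,band", [
    (0.0, "negligible"), (0.19, "negligible"), (0.2, "small"), (-0.35, "small"),
    (0.49, "small"), (0.5, "medium"), (-0.79, "medium"), (0.8, "large"), (-2.0, "large"),
])
def test_effect_bands_honor_the_standard_cutoffs(d, band):
    assert sm.effect_band(d) == band


def test_shared_resample_pairing_detects_a_planted_difference():
    rng = np.random.default_rng(7)
    n = 200
    labels = np.array([0, 1] * (n // 2))
    good = np.clip(labels * 0.7 + rng.uniform(0, 0.4, n), 0, 1)
    bad = rng.uniform(0, 1, n)
    result = sm.paired_model_comparison(frame(labels, good), frame(labels, bad),
                                        metric="auc", n_boot=300, seed=0)
    assert result.p_value < 1e-6
    assert result.cohens_d > 0.8


def test_bootstrap_resamples_preserve_class_counts():
    labels = np.array([0] * 6 + [1] * 4)
    preds = frame(labels, np.linspace(0, 1, 10))
    samples = bootstrap_metric_samples(preds, n_boot=50, seed=0)
    assert len(samples) == 50
    assert samples["auc"].between(0, 1).all()


def test_ablation_arms_differ_only_in_pooling(small_dataset):
    trainval, test = sm.split_by_patient(small_dataset, 0.7, True, seed=2)
    tr, val = sm.split_by_patient(trainval, 0.8, True, seed=2)
    result = sm.ablation_run(tr, val, test, poolings=("mean", "attention"),
                             train_config=sm.TrainConfig(lr=1e-3, epochs=2, seed=2),
                             n_boot=50)
    configs = result.arm_configs
    for pooling, cfg in configs.items():
        assert cfg["pooling"] == pooling
        stripped = {k: v for k, v in cfg.items() if k != "pooling"}
        reference = {k: v for k, v in configs["attention"].items() if k != "pooling"}
        assert stripped == reference
    assert set(result.reports) == {"mean", "attention"}
    assert "attention_vs_mean" in result.comparisons
    table = result.table()
    assert list(table.columns) == ["pooling", "accuracy", "precision",
                                   "recall", "f1", "auc"]
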