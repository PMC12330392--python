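"""Evaluation: classification metrics with bootstrap CIs and model comparison.

Point estimates use the usual confusion-matrix definitions at a fixed
decision threshold (ties resolved as probability >= threshold -> positive);
AUC is the area under the ROC curve, equal to the normalized Mann-Whitney
U statistic with ties counted one half.  95% confidence intervals come from
a stratified patient-level percentile bootstrap (class counts preserved in
every resample).  Two models are compared with a two-sided paired t-test
and Cohen's d for paired data (mean difference over SD of differences),
the pairing unit being per-resample metric values on a *shared* set of
bootstrap resamples.  Effect sizes are banded at the conventional
0.2 / 0.5 / 0.8 cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ConfigurationError
from .model import MILModel
from .train import TrainConfig, train

__all__ = [
    "PointCI", "MetricsReport", "ComparisonResult", "AblationResult",
    "predict_bags", "compute_metrics", "roc_points", "auc_score",
    "bootstrap_metric_samples", "paired_comparison", "paired_model_comparison",
    "effect_band", "ablation_run",
]


class PointCI(NamedTuple):
    point: float
    lower: float
    upper: float


@dataclass
class MetricsReport:
    accuracy: PointCI
    precision: PointCI
    recall: PointCI
    f1: PointCI
    auc: PointCI
    threshold: float
    n_patients: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {}
        for name in ("accuracy", "precision", "recall", "f1", "auc"):
            ci = getattr(self, name)
            out[name] = {"point": ci.point, "ci95": [ci.lower, ci.upper]}
        out["threshold"] = self.threshold
        out["n_patients"] = self.n_patients
        out["flags"] = list(self.flags)
        return out


@dataclass
class ComparisonResult:
    p_value: float
    cohens_d: float
    effect_band: str
    n: int
    mean_diff: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"p_value": self.p_value, "cohens_d": self.cohens_d,
                "effect_band": self.effect_band, "n": self.n,
                "mean_diff": self.mean_diff, "degenerate": self.degenerate}


def predict_bags(model: MILModel, bags) -> pd.DataFrame:
    """One prediction row per patient: columns patient_id, label, probability."""
    rows = [(b.patient_id, int(b.bag_label), model.predict(b).probability)
            for b in bags]
    return pd.DataFrame(rows, columns=["patient_id", "label", "probability"])


def _check_predictions(preds: pd.DataFrame):
    labels = preds["label"].to_numpy(dtype=int)
    probs = preds["probability"].to_numpy(dtype=float)
    if preds["patient_id"].duplicated().any():
        raise ConfigurationError("prediction set must have one row per patient")
    if not np.isin(labels, (0, 1)).all():
        raise ConfigurationError("labels must be binary {0, 1}")
    if ((probs < 0) | (probs > 1)).any():
        raise ConfigurationError("probabilities must lie in [0, 1]")
    return labels, probs


def _counts(labels, preds_bin):
    tp = int(np.sum((preds_bin == 1) & (labels == 1)))
    fp = int(np.sum((preds_bin == 1) & (labels == 0)))
    fn = int(np.sum((preds_bin == 0) & (labels == 1)))
    tn = int(np.sum((preds_bin == 0) & (labels == 0)))
    return tp, fp, fn, tn


def auc_score(labels: np.ndarray, probs: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney with average ranks; ties count 1/2)."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined when only one class is present")
    ranks = stats.rankdata(probs)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(preds: pd.DataFrame):
    """Monotone ROC curve from (0,0) to (1,1) plus its trapezoidal AUC."""
    labels, probs = _check_predictions(preds)
    fpr, tpr, _ = _sk_roc_curve(labels, probs, drop_intermediate=False)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def _point_metrics(labels, probs, threshold):
    preds_bin = (probs >= threshold).astype(int)
    tp, fp, fn, tn = _counts(labels, preds_bin)
    n = labels.size
    flags = []
    accuracy = (tp + tn) / n
    if tp + fp == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "auc": auc_score(labels, probs)}, flags


def _stratified_resample_indices(labels: np.ndarray, n_boot: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """(n_boot, n) index matrix preserving per-class patient counts."""
    parts = []
    for cls in (0, 1):
        idx = np.where(labels == cls)[0]
        draw = rng.integers(0, idx.size, size=(n_boot, idx.size))
        parts.append(idx[draw])
    return np.concatenate(parts, axis=1)


def bootstrap_metric_samples(preds: pd.DataFrame, threshold: float = 0.5,
                             n_boot: int = 1000, seed: int = 0,
                             indices: np.ndarray | None = None) -> pd.DataFrame:
    """Per-resample metrics; pass a shared ``indices`` matrix to pair models."""
    labels, probs = _check_predictions(preds)
    if indices is None:
        indices = _stratified_resample_indices(
            labels, n_boot, np.random.default_rng(seed))
    lab = labels[indices]                       # (n_boot, n)
    prb = probs[indices]
    pred_bin = (prb >= threshold).astype(int)
    tp = ((pred_bin == 1) & (lab == 1)).sum(axis=1).astype(float)
    fp = ((pred_bin == 1) & (lab == 0)).sum(axis=1).astype(float)
    fn = ((pred_bin == 0) & (lab == 1)).sum(axis=1).astype(float)
    tn = ((pred_bin == 0) & (lab == 0)).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        accuracy = (tp + tn) / lab.shape[1]
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    n_pos = (lab == 1).sum(axis=1)
    n_neg = (lab == 0).sum(axis=1)
    ranks = stats.rankdata(prb, axis=1)
    pos_rank_sum = np.where(lab == 1, ranks, 0.0).sum(axis=1)
    auc = (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return pd.DataFrame({"accuracy": accuracy, "precision": precision,
                         "recall": recall, "f1": f1, "auc": auc})


def compute_metrics(preds: pd.DataFrame, threshold: float = 0.5,
                    n_boot: int = 1000, seed: int = 0) -> MetricsReport:
    """Point estimates plus stratified percentile-bootstrap 95% CIs."""
    labels, probs = _check_predictions(preds)
    if len(set(labels.tolist())) < 2:
        raise ValueError("metrics require both classes in the truth labels")
    points, flags = _point_metrics(labels, probs, threshold)
    samples = bootstrap_metric_samples(preds, threshold=threshold,
                                       n_boot=n_boot, seed=seed)
    cis = {}
    for name in ("accuracy", "precision", "recall", "f1", "auc"):
        lo, hi = np.percentile(samples[name].to_numpy(), [2.5, 97.5])
        cis[name] = PointCI(point=float(points[name]), lower=float(lo), upper=float(hi))
    return MetricsReport(threshold=threshold, n_patients=labels.size,
                         flags=flags, **cis)


def effect_band(d: float) -> str:
    """Band |d| at the conventional 0.2 / 0.5 / 0.8 cutoffs."""
    magnitude = abs(d)
    if magnitude < 0.2:
        return "negligible"
    if magnitude < 0.5:
        return "small"
    if magnitude < 0.8:
        return "medium"
    return "large"


def paired_comparison(samples_a, samples_b) -> ComparisonResult:
    """Two-sided paired t-test plus Cohen's d = mean(diff)/sd(diff)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ConfigurationError("paired samples must be equal-length 1-D with n >= 2")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return ComparisonResult(p_value=float("nan"), cohens_d=0.0,
                                effect_band=effect_band(0.0), n=a.size,
                                mean_diff=mean_diff, degenerate=True)
    d = mean_diff / sd
    _, p = stats.ttest_rel(a, b)
    return ComparisonResult(p_value=float(p), cohens_d=float(d),
                            effect_band=effect_band(d), n=a.size,
                            mean_diff=mean_diff)


def paired_model_comparison(preds_a: pd.DataFrame, preds_b: pd.DataFrame,
                            metric: str = "auc", threshold: float = 0.5,
                            n_boot: int = 1000, seed: int = 0) -> ComparisonResult:
    """Compare two models on identical patients via shared bootstrap resamples."""
    merged = preds_a.merge(preds_b, on="patient_id", suffixes=("_a", "_b"))
    if len(merged) != len(preds_a) or len(merged) != len(preds_b):
        raise ConfigurationError("models must be evaluated on the same patients")
    if (merged["label_a"] != merged["label_b"]).any():
        raise ConfigurationError("labels disagree between the two prediction sets")
    labels = merged["label_a"].to_numpy(dtype=int)
    indices = _stratified_resample_indices(labels, n_boot, np.random.default_rng(seed))
    frame_a = merged[["patient_id", "label_a", "probability_a"]].rename(
        columns={"label_a": "label", "probability_a": "probability"})
    frame_b = merged[["patient_id", "label_b", "probability_b"]].rename(
        columns={"label_b": "label", "probability_b": "probability"})
    sa = bootstrap_metric_samples(frame_a, threshold=threshold, indices=indices)
    sb = bootstrap_metric_samples(frame_b, threshold=threshold, indices=indices)
    return paired_comparison(sa[metric].to_numpy(), sb[metric].to_numpy())


@dataclass
class AblationResult:
    reports: dict[str, MetricsReport]
    predictions: dict[str, pd.DataFrame]
    comparisons: dict[str, ComparisonResult]
    arm_configs: dict[str, dict]

    def table(self) -> pd.DataFrame:
        rows = []
        for pooling, report in self.reports.items():
            row = {"pooling": pooling}
            for name in ("accuracy", "precision", "recall", "f1", "auc"):
                row[name] = getattr(report, name).point
            rows.append(row)
        return pd.DataFrame(rows)


def ablation_run(train_bags, val_bags, test_bags,
                 poolings=("max", "mean", "attention"),
                 encoder_spec=None, train_config: TrainConfig | None = None,
                 attn_hidden: int = 128, model_seed: int = 0,
                 threshold: float = 0.5, n_boot: int = 1000,
                 eval_seed: int = 0) -> AblationResult:
    """Train one arm per pooling operator under an otherwise identical protocol.

    Each arm shares the data, encoder spec, initialization seed and training
    configuration; only the aggregation operator differs.  Attention is
    compared against every other arm by paired test on shared bootstrap
    resamples of the test AUC.
    """
    train_config = train_config or TrainConfig()
    reports, predictions, configs = {}, {}, {}
    for pooling in poolings:
        model = MILModel(encoder_spec=encoder_spec, pooling=pooling,
                         attn_hidden=attn_hidden, seed=model_seed)
        train(train_bags, val_bags, model, train_config)
        preds = predict_bags(model, test_bags)
        reports[pooling] = compute_metrics(preds, threshold=threshold,
                                           n_boot=n_boot, seed=eval_seed)
        predictions[pooling] = preds
        configs[pooling] = model.config()
    comparisons = {}
    if "attention" in reports:
        for pooling in reports:
            if pooling == "attention":
                continue
            comparisons[f"attention_vs_{pooling}"] = paired_model_comparison(
                predictions["attention"], predictions[pooling],
                metric="auc", threshold=threshold, n_boot=n_boot, seed=eval_seed)
    return AblationResult(reports=reports, predictions=predictions,
                          comparisons=comparisons, arm_configs=configs)
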