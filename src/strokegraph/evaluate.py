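"""Segmentation metrics, ROC, patient-level CV, noise injection, significance.

Metric conventions for imbalanced lesion masks: all metrics are computed
from pixel-wise confusion counts; when a denominator-defining reference set
is empty (e.g. both masks empty for DSC, no true lesion for sensitivity)
the metric is defined as 1.0 -- a prediction cannot do better than matching
an empty reference.  Under globally pooled counts the identity
J = D / (2 - D) between Jaccard and Dice holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats
from sklearn import metrics as _sk_metrics

from .errors import ConfigurationError, InputError

__all__ = [
    "MetricsReport",
    "FoldAssignment",
    "NoiseSpec",
    "confusion_counts",
    "dsc",
    "jaccard",
    "sensitivity",
    "precision",
    "accuracy",
    "metrics_from_counts",
    "roc_curve",
    "patient_kfold",
    "add_awgn",
    "fold_significance",
    "robustness_sweep",
]


@dataclass
class MetricsReport:
    """Bundle of segmentation metrics with fold provenance."""

    dsc: float
    jaccard: float
    sensitivity: float
    precision: float
    accuracy: float
    n_slices: int = 0
    fold_id: int = -1
    aggregation: str = "global-pooled"

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc, "jaccard": self.jaccard,
            "sensitivity": self.sensitivity, "precision": self.precision,
            "accuracy": self.accuracy, "n_slices": self.n_slices,
            "fold_id": self.fold_id, "aggregation": self.aggregation,
        }


@dataclass
class FoldAssignment:
    """Patient -> fold mapping for leakage-free cross-validation."""

    k: int
    mapping: dict[str, int]

    def patients_in_fold(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.mapping.items() if f == fold)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a target SNR (dB)."""

    snr_db: float
    seed: int = 0


def _check_masks(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred_mask, true_mask) -> tuple[int, int, int, int]:
    """Pixel-wise (TP, FP, FN, TN)."""
    pred, truth = _check_masks(pred_mask, true_mask)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return tp, fp, fn, tn


def _safe_ratio(num: float, den: float) -> float:
    # 0/0 -> 1.0: the reference set defining the denominator is empty.
    return num / den if den > 0 else 1.0


def dsc(pred_mask, true_mask) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN); both-empty -> 1.0."""
    tp, fp, fn, _ = confusion_counts(pred_mask, true_mask)
    return _safe_ratio(2.0 * tp, 2.0 * tp + fp + fn)


def jaccard(pred_mask, true_mask) -> float:
    """Jaccard index TP / (TP + FP + FN); both-empty -> 1.0."""
    tp, fp, fn, _ = confusion_counts(pred_mask, true_mask)
    return _safe_ratio(float(tp), float(tp + fp + fn))


def sensitivity(pred_mask, true_mask) -> float:
    """Recall TP / (TP + FN); empty truth -> 1.0."""
    tp, _, fn, _ = confusion_counts(pred_mask, true_mask)
    return _safe_ratio(float(tp), float(tp + fn))


def precision(pred_mask, true_mask) -> float:
    """TP / (TP + FP); empty prediction -> 1.0."""
    tp, fp, _, _ = confusion_counts(pred_mask, true_mask)
    return _safe_ratio(float(tp), float(tp + fp))


def accuracy(pred_mask, true_mask) -> float:
    """(TP + TN) / total."""
    tp, fp, fn, tn = confusion_counts(pred_mask, true_mask)
    return (tp + tn) / float(tp + fp + fn + tn)


def metrics_from_counts(tp: float, fp: float, fn: float, tn: float,
                        n_slices: int = 0, fold_id: int = -1) -> MetricsReport:
    """Build a globally pooled MetricsReport from summed confusion counts."""
    return MetricsReport(
        dsc=_safe_ratio(2.0 * tp, 2.0 * tp + fp + fn),
        jaccard=_safe_ratio(float(tp), float(tp + fp + fn)),
        sensitivity=_safe_ratio(float(tp), float(tp + fn)),
        precision=_safe_ratio(float(tp), float(tp + fp)),
        accuracy=(tp + tn) / float(tp + fp + fn + tn),
        n_slices=n_slices, fold_id=fold_id, aggregation="global-pooled")


def roc_curve(node_probs, node_labels):
    """Threshold sweep over lesion probabilities.

    Returns ``(fpr, tpr, thresholds, auc)``; requires both classes present.
    """
    probs = np.asarray(node_probs, dtype=np.float64)
    labels = np.asarray(node_labels)
    present = np.unique(labels)
    for cls in (0, 1):
        if cls not in present:
            raise InputError(f"ROC undefined: class {cls} absent from labels")
    fpr, tpr, thr = _sk_metrics.roc_curve(labels, probs)
    return fpr, tpr, thr, float(_sk_metrics.auc(fpr, tpr))


def patient_kfold(patient_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign whole patients to k folds (sizes differing by at most one).

    Every slice of a patient therefore lands in the same fold, which is what
    prevents train/test leakage of correlated slices.
    """
    patients = sorted(set(map(str, patient_ids)))
    if k > len(patients):
        raise ConfigurationError(
            f"k={k} exceeds number of patients ({len(patients)})")
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    mapping = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            mapping[patients[idx]] = fold
    return FoldAssignment(k=k, mapping=mapping)


def add_awgn(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add white Gaussian noise at a target SNR.

    Noise variance is P_signal / 10^(SNR_db/10) with the signal power taken
    as the mean squared intensity over the whole slice.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite values")
    p_signal = float(np.mean(image ** 2))
    if p_signal == 0.0:
        raise InputError("signal power is zero; SNR undefined for an all-zero image")
    sigma = np.sqrt(p_signal / 10.0 ** (spec.snr_db / 10.0))
    rng = np.random.default_rng(spec.seed)
    return image + rng.normal(0.0, sigma, size=image.shape)


def fold_significance(metric_per_fold_a, metric_per_fold_b) -> tuple[float, float]:
    """Two-sided paired t-test and Wilcoxon signed-rank p-values.

    When every paired difference is zero both tests are degenerate and the
    sentinel p-value 1.0 is returned for the affected test.
    """
    a = np.asarray(metric_per_fold_a, dtype=np.float64)
    b = np.asarray(metric_per_fold_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("fold metrics must be equal-length 1-D sequences")
    if len(a) < 5:
        raise InputError("need at least 5 paired folds")
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0, 1.0
    t_res = _scipy_stats.ttest_rel(a, b)
    t_p = float(t_res.pvalue)
    if np.isnan(t_p):  # zero-variance non-zero shift: t-test degenerate
        t_p = 0.0
    try:
        w_res = _scipy_stats.wilcoxon(a, b)
        w_p = float(w_res.pvalue)
    except ValueError:
        w_p = 1.0
    return t_p, w_p


def robustness_sweep(model, test_samples, snr_grid=None, *,
                     pre_cfg=None, graph_cfg=None, seed: int = 0):
    """Re-run the full pipeline on noise-degraded copies of a clean test set.

    For each SNR in the grid (default -4..5 dB) white Gaussian noise is
    injected into the raw HU-scale slices *before* preprocessing and graph
    construction, the trained model predicts node labels, and globally
    pooled pixel metrics are reported.  The clean (no-noise) row is included
    as the reference under the key ``None``.
    """
    from .pipeline import evaluate_samples  # lazy: pipeline builds on this module

    if snr_grid is None:
        snr_grid = list(range(-4, 6))
    snr_grid = list(snr_grid)
    if len(snr_grid) == 0:
        raise ConfigurationError("empty SNR grid")
    rows: dict = {}
    rows[None] = evaluate_samples(model, test_samples, pre_cfg=pre_cfg,
                                  graph_cfg=graph_cfg)
    for i, snr in enumerate(snr_grid):
        noisy = []
        for j, s in enumerate(test_samples):
            spec = NoiseSpec(snr_db=snr, seed=seed + 10007 * i + j)
            noisy.append(type(s)(image=add_awgn(s.image, spec), mask=s.mask,
                                 patient_id=s.patient_id,
                                 slice_index=s.slice_index, split=s.split))
        rows[float(snr)] = evaluate_samples(model, noisy, pre_cfg=pre_cfg,
                                            graph_cfg=graph_cfg)
    return rows
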