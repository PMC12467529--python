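"""Evaluation protocol: stratified splitting, k-fold cross-validation,
confusion-matrix metrics, rank-based AUC, paired McNemar tests and the
feature-dimensionality sweep."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2

from .catalog import FeatureCatalog
from .cohort import CohortTable
from .config import RunConfig
from .workflow import FittedModel, fit, predict


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: str

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def confusion(actual, predicted, positive_label: str) -> ConfusionMatrix:
    """Standard 2x2 counts; any label outside the observed pair is an error."""
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    labels = set(np.unique(np.r_[a, p]).tolist())
    extra = labels - set(np.unique(a).tolist()) - {positive_label}
    if len(labels) > 2:
        raise ValueError(f"more than two labels present: {sorted(labels)}")
    del extra
    pos_a = a == positive_label
    pos_p = p == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_a & pos_p)),
        fp=int(np.sum(~pos_a & pos_p)),
        fn=int(np.sum(pos_a & ~pos_p)),
        tn=int(np.sum(~pos_a & ~pos_p)),
        positive_label=positive_label,
    )


def binary_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy / precision / recall / F1 from a confusion matrix.

    Undefined metrics (zero denominator) are reported as None, never 0.
    """
    total = cm.total
    accuracy = (cm.tp + cm.tn) / total if total else None
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def roc_auc(scores, positive_mask) -> float:
    """Mann-Whitney rank AUC: P(score_pos > score_neg) with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(positive_mask, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def train_test_split(
    cohort: CohortTable, train_fraction: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Stratified, seeded split preserving class balance."""
    if cohort.labels is None:
        raise ValueError("splitting requires labels")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    lab = cohort.labels.to_numpy()
    for cls in (cohort.positive_label, cohort.negative_label):
        idx = np.flatnonzero(lab == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return cohort.subset(sorted(train_idx)), cohort.subset(sorted(test_idx))


def kfold_indices(
    labels: np.ndarray, positive_label: str, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, seeded, disjoint folds covering all records."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has fewer records than folds")
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    folds = []
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        folds.append((train, test))
    return folds


@dataclass
class CVReport:
    per_fold: list[MetricsReport]

    def summary(self) -> dict:
        out: dict[str, dict[str, float]] = {}
        for key in ("accuracy", "precision", "recall", "f1", "auc"):
            vals = [getattr(r, key) for r in self.per_fold]
            vals = [v for v in vals if v is not None]
            if not vals:
                continue
            arr = np.asarray(vals, dtype=float)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            out[key] = {"mean": float(arr.mean()), "sd": sd}
        return out


def evaluate_split(
    model: FittedModel, test: CohortTable
) -> MetricsReport:
    """Score a held-out cohort and compute all metrics including AUC.

    The continuous score for the ROC is oriented as ``OWODc - OWOD`` so
    that larger values indicate the positive class (records at or below
    the cut-off are classified positive).
    """
    scored = predict(model, test)
    actual = test.labels.to_numpy()
    cm = confusion(actual, scored["predicted"].to_numpy(), test.positive_label)
    report = binary_metrics(cm)
    s = model.cutoff.owod_c - scored["owod"].to_numpy()
    report.auc = roc_auc(s, actual == test.positive_label)
    return report


def run_cv(
    cohort: CohortTable,
    config: RunConfig,
    catalog: FeatureCatalog | None = None,
    k: int | None = None,
) -> CVReport:
    """Per-fold fit (objective params + cut-off) and evaluation."""
    if cohort.labels is None:
        raise ValueError("cross-validation requires labels")
    k = k or config.folds
    folds = kfold_indices(
        cohort.labels.to_numpy(), cohort.positive_label, k, config.seed
    )
    reports = []
    for train_idx, test_idx in folds:
        train = cohort.subset(train_idx)
        test = cohort.subset(test_idx)
        model = fit(train, config, catalog)
        reports.append(evaluate_split(model, test))
    return CVReport(per_fold=reports)


def mcnemar(pred_a, pred_b, actual) -> tuple[float, float]:
    """McNemar's paired test on two classifiers' predictions.

    Returns (statistic, p).  With fewer than 25 discordant pairs the exact
    two-sided binomial test is used and the statistic is the smaller
    discordant count; otherwise the continuity-corrected chi-square.
    """
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    y = np.asarray(actual)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("prediction and actual vectors must align")
    a_ok = a == y
    b_ok = b == y
    n_b = int(np.sum(a_ok & ~b_ok))  # A correct, B wrong
    n_c = int(np.sum(~a_ok & b_ok))  # A wrong, B correct
    n_disc = n_b + n_c
    if n_disc == 0:
        return 0.0, 1.0
    if n_disc < 25:
        k = min(n_b, n_c)
        p = 2.0 * binom.cdf(k, n_disc, 0.5)
        if n_b == n_c:  # both tails coincide
            p = 1.0
        return float(k), float(min(p, 1.0))
    stat = (abs(n_b - n_c) - 1) ** 2 / n_disc
    p = float(chi2.sf(stat, df=1))
    return float(stat), p


def feature_subset_experiment(
    cohort: CohortTable,
    config: RunConfig,
    order: list[str],
    sizes=(8, 12, 16, 20),
    catalog: FeatureCatalog | None = None,
) -> pd.DataFrame:
    """Cross-validated metrics for nested feature subsets of growing size."""
    if max(sizes) > len(order):
        raise ValueError(
            f"largest size {max(sizes)} exceeds the {len(order)} ordered features"
        )
    rows = []
    for size in sizes:
        sub_cfg = RunConfig(**{**config.to_dict(), "features": order[:size]})
        report = run_cv(cohort, sub_cfg, catalog)
        summary = report.summary()
        row = {"n_features": size}
        for key, ms in summary.items():
            row[f"{key}_mean"] = ms["mean"]
            row[f"{key}_sd"] = ms["sd"]
        rows.append(row)
    return pd.DataFrame(rows)
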