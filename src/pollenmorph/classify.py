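"""Genus discrimination: repeated random-split SVM cross-validation and the
1-s.d. size rule.

The cross-validation protocol mirrors the study design: 99 iterations of a
randomised (simple, unstratified) 80:20 split into training and test sets; an
RBF-kernel support vector machine (C = 1, gamma = "scale"; the instrument
study does not publish hyperparameters, so these defaults are fixed here and
overridable) trained on features standardized on the training split only;
accuracy is the fraction of correct test-set predictions. Because the classes
are imbalanced, per-class recall and the majority-class baseline are reported
alongside accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import FEATURE_COLUMNS
from .morphometry import CORE_FEATURE_NAMES
from .ordination import SummaryStats

__all__ = ["CVConfig", "CVReport", "svm_cv", "feature_subset",
           "size_rule_classify", "INDETERMINATE"]

INDETERMINATE = "indeterminate"


@dataclass
class CVConfig:
    """Configuration of the repeated random-split SVM experiment."""

    n_iter: int = 99
    train_frac: float = 0.8
    feature_set: str = "all50"  # "core7" | "all50"
    view_set: str = "both"  # "polar_only" | "both"
    seed: int = 0
    stratified: bool = False
    svm_c: float = 1.0
    svm_gamma: str = "scale"

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie strictly in (0, 1)")
        if self.feature_set not in ("core7", "all50"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.view_set not in ("polar_only", "both"):
            raise ValueError(f"unknown view_set {self.view_set!r}")


@dataclass
class CVReport:
    """Per-iteration and aggregate accuracy of the SVM experiment (percent)."""

    accuracies: np.ndarray  # one accuracy (%) per iteration
    mean_accuracy: float
    sd_accuracy: float
    pooled_accuracy: float  # accuracy over all test predictions pooled
    per_class_recall: Dict[str, float]  # mean recall (%) per genus
    majority_baseline: float  # % of the majority class
    config: CVConfig

    def to_dict(self) -> dict:
        return {
            "accuracies": [float(a) for a in self.accuracies],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "per_class_recall": dict(self.per_class_recall),
            "majority_baseline": self.majority_baseline,
            "config": {
                "n_iter": self.config.n_iter,
                "train_frac": self.config.train_frac,
                "feature_set": self.config.feature_set,
                "view_set": self.config.view_set,
                "seed": self.config.seed,
                "stratified": self.config.stratified,
                "svm_c": self.config.svm_c,
                "svm_gamma": self.config.svm_gamma,
            },
        }


def feature_subset(table: pd.DataFrame, feature_set: str,
                   view_set: str = "both") -> pd.DataFrame:
    """Restrict a feature table to a feature set and view set."""
    if view_set == "polar_only":
        if "view" not in table.columns:
            raise ValueError("view_set='polar_only' requires a 'view' column")
        table = table.loc[table["view"] == "polar"]
    cols = list(CORE_FEATURE_NAMES) if feature_set == "core7" \
        else list(FEATURE_COLUMNS)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    return table


def svm_cv(features: pd.DataFrame, labels: Sequence[str],
           config: Optional[CVConfig] = None) -> CVReport:
    """Repeated random-split SVM cross-validation.

    ``features`` must contain only feature columns (subset with
    :func:`feature_subset` first and drop identity columns, or pass a table
    whose non-numeric columns have been removed). Split ``i`` is seeded with
    ``config.seed + i``; standardization is fit on each training split only.
    """
    config = config or CVConfig()
    config.validate()
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(
            f"svm_cv requires two label classes, got {list(classes)}"
        )
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains missing/non-finite values")
    n = len(X)
    n_train = int(round(config.train_frac * n))
    if not 0 < n_train < n:
        raise ValueError("train fraction leaves an empty train or test set")

    accs: List[float] = []
    correct_pool = 0
    total_pool = 0
    recall_sums = {c: 0.0 for c in classes}
    recall_counts = {c: 0 for c in classes}
    for i in range(config.n_iter):
        rng = np.random.default_rng(config.seed + i)
        if config.stratified:
            train_idx: List[int] = []
            for c in classes:
                idx_c = np.flatnonzero(y == c)
                k = int(round(config.train_frac * len(idx_c)))
                train_idx.extend(rng.permutation(idx_c)[:k])
            train = np.zeros(n, dtype=bool)
            train[np.asarray(train_idx)] = True
        else:
            perm = rng.permutation(n)
            train = np.zeros(n, dtype=bool)
            train[perm[:n_train]] = True
        if len(np.unique(y[train])) < 2:
            # a simple random split may miss a rare class entirely
            continue
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma,
                cache_size=500),
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[~train])
        truth = y[~train]
        accs.append(100.0 * float((pred == truth).mean()))
        correct_pool += int((pred == truth).sum())
        total_pool += len(truth)
        for c in classes:
            m = truth == c
            if m.any():
                recall_sums[c] += float((pred[m] == c).mean())
                recall_counts[c] += 1
    if not accs:
        raise ValueError("no iteration produced a two-class training split")
    accs_arr = np.asarray(accs)
    return CVReport(
        accuracies=accs_arr,
        mean_accuracy=float(accs_arr.mean()),
        sd_accuracy=float(accs_arr.std(ddof=1)) if len(accs_arr) > 1 else 0.0,
        pooled_accuracy=100.0 * correct_pool / total_pool,
        per_class_recall={
            str(c): 100.0 * recall_sums[c] / max(recall_counts[c], 1)
            for c in classes
        },
        majority_baseline=100.0 * float(counts.max()) / n,
        config=config,
    )


def size_rule_classify(e_values: Sequence[float], stats_a: SummaryStats,
                       stats_b: SummaryStats, label_a: str = "a",
                       label_b: str = "b") -> List[str]:
    """Assign grains to a genus by the 1-s.d. equatorial-diameter ranges.

    A grain is labelled if its E falls inside exactly one of the two 1-s.d.
    ranges; grains inside both (overlap) or neither are ``indeterminate``.
    """
    lo_a, hi_a = stats_a.range_1sd
    lo_b, hi_b = stats_b.range_1sd
    out = []
    for e in np.asarray(e_values, dtype=float):
        in_a = lo_a <= e <= hi_a
        in_b = lo_b <= e <= hi_b
        if in_a and not in_b:
            out.append(label_a)
        elif in_b and not in_a:
            out.append(label_b)
        else:
            out.append(INDETERMINATE)
    return out
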