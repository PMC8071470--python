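"""SVM classification of functionome GSR patterns under repeated CV.

Case-vs-control classification uses a radial-basis-function support vector
machine on the GSR columns as-is (they already live in [0, 1]).  Folds are
stratified by class — cohorts here can be heavily unbalanced — and the
whole k-fold split is repeated with fresh seeded shuffles.  Per repeat the
out-of-fold predictions are pooled into one confusion matrix, giving one
sensitivity/specificity/accuracy triple and one AUC from the pooled
decision scores; the report carries the mean and SD over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .gsr import Functionome

__all__ = ["ClassificationReport", "confusion_metrics", "cv_classify"]


@dataclass
class ClassificationReport:
    group: str
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    accuracy_mean: float
    accuracy_sd: float
    auc: float
    n_repeats: int
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": self.group,
                    "sensitivity": self.sensitivity_mean,
                    "sensitivity_sd": self.sensitivity_sd,
                    "specificity": self.specificity_mean,
                    "specificity_sd": self.specificity_sd,
                    "accuracy": self.accuracy_mean,
                    "accuracy_sd": self.accuracy_sd,
                    "auc": self.auc,
                    "n_repeats": self.n_repeats,
                    "n_folds": self.n_folds,
                }
            ]
        )


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("sensitivity/specificity undefined: empty class")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    return sens, spec, acc


def cv_classify(
    f: Functionome,
    labels: pd.Series | dict,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    group: str = "case",
    kernel: str = "rbf",
    C: float = 1.0,
) -> ClassificationReport:
    """Repeated stratified k-fold SVM classification of GSR patterns.

    Positive class is ``case``.  AUC is computed per repeat from the pooled
    out-of-fold decision scores, then averaged over repeats.  Fully
    reproducible under a fixed seed.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(f.sample_ids)
    y = (labels == "case").to_numpy()
    X = f.gsr.to_numpy(dtype=float)
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    if min(n_case, n_ctrl) < n_folds:
        raise ValueError(
            f"smallest class has {min(n_case, n_ctrl)} samples, fewer than "
            f"{n_folds} folds; reduce n_folds"
        )
    rng = np.random.default_rng(seed)
    sens, spec, acc, aucs = [], [], [], []
    for _ in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        pred = np.zeros_like(y)
        score = np.zeros(len(y), dtype=float)
        for train, test in skf.split(X, y):
            clf = SVC(kernel=kernel, C=C, gamma="scale")
            clf.fit(X[train], y[train])
            pred[test] = clf.predict(X[test])
            score[test] = clf.decision_function(X[test])
        tp = int(np.sum(pred & y))
        tn = int(np.sum(~pred & ~y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        se, sp, ac = confusion_metrics(tp, fp, tn, fn)
        sens.append(se)
        spec.append(sp)
        acc.append(ac)
        if np.ptp(score) == 0:
            aucs.append(0.5)  # constant scores carry no ranking information
        else:
            aucs.append(roc_auc_score(y, score))

    def _ms(v):
        a = np.asarray(v, dtype=float)
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    sens_m, sens_s = _ms(sens)
    spec_m, spec_s = _ms(spec)
    acc_m, acc_s = _ms(acc)
    return ClassificationReport(
        group=group,
        sensitivity_mean=sens_m,
        sensitivity_sd=sens_s,
        specificity_mean=spec_m,
        specificity_sd=spec_s,
        accuracy_mean=acc_m,
        accuracy_sd=acc_s,
        auc=float(np.mean(aucs)),
        n_repeats=n_repeats,
        n_folds=n_folds,
    )
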