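"""Linear-SVM separability of condition beta maps.

Tests whether ground-truth and inference maps (or model-condition and
empathic-accuracy maps) are linearly separable at a given intensity level:
a linear SVM (C = 1) under leave-one-subject-out CV — both of a subject's
maps held out together so subject identity cannot leak — with fold-pooled
decision values summarized as an ROC curve and AUC, a two-sided binomial
test of accuracy against chance (0.5), and a subject-level bootstrap of
the classifier's voxel weights with BH-FDR thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from .glm import BetaMapSet
from .lasso_pcr import BootstrapResult, fdr_bh

logger = logging.getLogger(__name__)


@dataclass
class SVMResult:
    """Per-level binary classification summary."""

    level: object
    accuracy: float
    accuracy_se: float        # binomial SE at the observed accuracy
    p_binomial: float         # two-sided vs chance 0.5
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    fold_predictions: np.ndarray
    fold_decision_values: np.ndarray
    labels: np.ndarray
    subjects: list[str]
    weights: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        assert 0.0 <= self.accuracy <= 1.0
        assert 0.0 <= self.auc <= 1.0


def roc_curve(decision_values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoid AUC from pooled decision values.

    Sweeps thresholds over the unique decision values; ties contribute
    simultaneous TPR/FPR steps (midpoint convention), so the AUC equals
    the normalized Mann-Whitney U statistic. Returns (fpr, tpr, auc).
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = skmetrics.roc_curve(y, decision_values)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def _loso_svm(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
              C: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-subject-out linear SVM; returns (predictions, decision values)."""
    preds = np.empty(y.size, dtype=int)
    dvals = np.empty(y.size)
    for g in np.unique(groups):
        test = groups == g
        if np.unique(y[~test]).size < 2:
            raise ValueError("a training fold contains a single class")
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[~test], y[~test])
        preds[test] = clf.predict(X[test])
        dvals[test] = clf.decision_function(X[test])
    return preds, dvals


def _stack_pair(set_a: BetaMapSet, set_b: BetaMapSet, level_a: object,
                level_b: object | None = None):
    """Paired stacking of one map per subject per set at the given level(s)."""
    level_b = level_a if level_b is None else level_b
    subjects = [s for s in set_a.subjects()
                if (s, level_a) in set_a.maps and (s, level_b) in set_b.maps]
    if not subjects:
        raise ValueError("no subjects with paired maps at this level")
    X = np.vstack([np.stack([set_a.maps[(s, level_a)], set_b.maps[(s, level_b)]])
                   for s in subjects])
    y = np.tile([0, 1], len(subjects))
    groups = np.repeat(subjects, 2)
    return X, y, groups, subjects


def _summarize(X, y, groups, subjects, level, C) -> SVMResult:
    preds, dvals = _loso_svm(X, y, groups, C)
    acc = float(np.mean(preds == y))
    n = y.size
    p = float(stats.binomtest(int(np.sum(preds == y)), n, 0.5, alternative="two-sided").pvalue)
    fpr, tpr, auc = roc_curve(dvals, y)
    full = SVC(kernel="linear", C=C).fit(X, y)
    return SVMResult(level=level, accuracy=acc,
                     accuracy_se=float(np.sqrt(acc * (1 - acc) / n)),
                     p_binomial=p, auc=auc, roc_fpr=fpr, roc_tpr=tpr,
                     fold_predictions=preds, fold_decision_values=dvals,
                     labels=y, subjects=list(subjects),
                     weights=full.coef_.ravel())


def train_svm_per_level(gt_maps: BetaMapSet, inf_maps: BetaMapSet,
                        level: int, C: float = 1.0) -> SVMResult:
    """Classify ground-truth vs inference maps at one intensity level.

    LOO-CV leaves out both of a subject's maps together; accuracy is the
    fraction of held-out maps labeled correctly, AUC comes from the
    fold-pooled decision values, and significance from a two-sided
    binomial test against 0.5. The reported weight map is from a fit on
    all pairs (solver: hinge-loss linear SVM, C as given).
    """
    X, y, groups, subjects = _stack_pair(gt_maps, inf_maps, level)
    return _summarize(X, y, groups, subjects, level, C)


def classify_vs_accuracy_maps(model_maps: BetaMapSet, ea_maps: BetaMapSet,
                              C: float = 1.0) -> dict[tuple[object, str], SVMResult]:
    """Separate each model-condition level from each empathic-accuracy tier.

    Runs the per-level SVM contract for every (intensity level, accuracy
    tier) combination present; returns ``{(level, tier): SVMResult}``.
    """
    results: dict[tuple[object, str], SVMResult] = {}
    levels = sorted({l for _, l in model_maps.maps}, key=str)
    tiers = sorted({t for _, t in ea_maps.maps}, key=str)
    for lvl in levels:
        for tier in tiers:
            X, y, groups, subjects = _stack_pair(model_maps, ea_maps, lvl, tier)
            results[(lvl, tier)] = _summarize(X, y, groups, subjects, (lvl, tier), C)
    return results


def bootstrap_svm_weights(gt_maps: BetaMapSet, inf_maps: BetaMapSet, level: int,
                          n_boot: int = 5000, q: float = 0.05, seed: int = 0,
                          C: float = 1.0) -> BootstrapResult:
    """Subject-level bootstrap of the linear-SVM voxel weights with BH-FDR."""
    X, y, groups, subjects = _stack_pair(gt_maps, inf_maps, level)
    rng = np.random.default_rng(seed)
    subjects = list(subjects)
    index = {s: np.flatnonzero(groups == s) for s in subjects}
    W = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        while True:
            draw = rng.choice(subjects, size=len(subjects), replace=True)
            if len(set(draw)) >= 2:
                break
        rows = np.concatenate([index[s] for s in draw])
        W[b] = SVC(kernel="linear", C=C).fit(X[rows], y[rows]).coef_.ravel()
    mean, sd = W.mean(axis=0), W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return BootstrapResult(boot_mean=mean, boot_sd=sd, z=z, p=p,
                           fdr_mask=fdr_bh(p, q), q=q, n_samples=n_boot)
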