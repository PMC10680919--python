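"""LASSO-regularized principal-components regression (LASSO-PCR) signatures.

The decoding model behind both brain signatures: beta maps are column-
centered, projected onto their principal components (at most ``lasso_num``
of them), an L1-penalized linear regression predicts intensity level from
the component scores (penalty chosen by mean-squared error along the
regularization path under internal cross-validation), and the component
coefficients are back-projected to voxel space. The result is a single
voxel weight vector plus intercept — a "signature" applied to any new map
as a dot product.

Also here: leave-one-subject-out cross-validation (LOO-CV) with the
prediction-outcome correlation metric, within-subject permutation tests of
that metric, and subject-level bootstrap of the voxel weights with
Benjamini-Hochberg FDR thresholding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.model_selection import GroupKFold, KFold
from statsmodels.stats.multitest import multipletests

from .glm import BetaMapSet

logger = logging.getLogger(__name__)

DEFAULT_LASSO_NUM = 120
DEFAULT_N_BOOT = 5000


@dataclass
class PatternModel:
    """A trained signature: voxel weights + intercept + training metadata.

    ``predict(map) = weights . map + intercept``. By construction the
    model applied to the mean training map returns the mean training
    outcome.
    """

    weights: np.ndarray
    intercept: float
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, maps: np.ndarray) -> np.ndarray | float:
        maps = np.asarray(maps, dtype=float)
        if maps.shape[-1] != self.weights.size:
            raise ValueError("map geometry does not match model weights")
        return maps @ self.weights + self.intercept


@dataclass
class CVResult:
    """Leave-one-subject-out predictions and per-subject correlations."""

    subject_ids: list[str]
    per_subject_r: np.ndarray
    predictions: dict[str, np.ndarray]
    actuals: dict[str, np.ndarray]
    skipped: list[str] = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_subject_r))

    @property
    def se_r(self) -> float:
        r = self.per_subject_r
        return float(np.std(r, ddof=1) / np.sqrt(r.size)) if r.size > 1 else float("nan")


@dataclass
class BootstrapResult:
    """Per-voxel bootstrap summary of signature weights."""

    boot_mean: np.ndarray
    boot_sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    q: float
    n_samples: int


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_lasso_pcr(maps: np.ndarray, outcomes: np.ndarray,
                  lasso_num: int = DEFAULT_LASSO_NUM, seed: int = 0,
                  *, n_folds: int = 5, groups: np.ndarray | None = None,
                  mask: np.ndarray | None = None,
                  affine: np.ndarray | None = None,
                  training_ids: list[str] | None = None) -> PatternModel:
    """Train a LASSO-PCR signature on stacked beta maps.

    ``maps`` is samples x voxels, ``outcomes`` the intensity level per
    sample. Components are computed by SVD of the column-centered data
    (no variance scaling); at most ``min(lasso_num, n_samples - 1)``
    components enter the LASSO step. The penalty is chosen by MSE along
    the default regularization path under ``n_folds``-fold internal CV;
    when per-sample ``groups`` (subject labels) are given the internal
    folds are grouped so a subject's maps never straddle a fold boundary.
    """
    X = np.asarray(maps, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("maps must be samples x voxels matching outcomes")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.unique(y).size < 2:
        raise ValueError("outcomes must take at least 2 distinct values")

    mean_map = X.mean(axis=0)
    Xc = X - mean_map
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    k = min(lasso_num, X.shape[0] - 1, rank)
    if k < 1:
        raise ValueError("training data has no variance")
    scores = U[:, :k] * S[:k]

    if groups is not None:
        n_groups = np.unique(np.asarray(groups)).size
        cv = list(GroupKFold(n_splits=min(n_folds, n_groups)).split(scores, y, groups))
    else:
        cv = KFold(n_splits=min(n_folds, X.shape[0]), shuffle=True, random_state=seed)
    lasso = LassoCV(cv=cv, random_state=seed, max_iter=50000)
    with warnings.catch_warnings():
        # near-null folds along the path stop at max_iter; the selected
        # model is refit and converges
        warnings.simplefilter("ignore", ConvergenceWarning)
        lasso.fit(scores, y)

    weights = Vt[:k].T @ lasso.coef_
    intercept = float(lasso.intercept_ - mean_map @ weights)
    meta = {
        "lasso_num": lasso_num,
        "n_components": int(k),
        "alpha": float(lasso.alpha_),
        "seed": seed,
        "n_samples": int(X.shape[0]),
        "centering": "column-mean only (no variance scaling)",
        "training_ids": list(training_ids) if training_ids else [],
    }
    return PatternModel(weights=weights, intercept=intercept, mask=mask,
                        affine=affine, metadata=meta)


def _stack_set(maps: BetaMapSet, subjects: list[str] | None = None):
    """Stack a BetaMapSet into (X, y, subject labels, provenance ids)."""
    subjects = maps.subjects() if subjects is None else subjects
    X, y, groups, prov = [], [], [], []
    for s in subjects:
        Xs, ys, ps = maps.subject_stack(s)
        X.append(Xs)
        y.append(ys)
        groups += [s] * len(ys)
        prov += ps
    return np.vstack(X), np.concatenate(y), np.array(groups), prov


def fit_signature(maps: BetaMapSet, lasso_num: int = DEFAULT_LASSO_NUM,
                  seed: int = 0) -> PatternModel:
    """Fit a signature on every subject x level map of a condition."""
    X, y, groups, prov = _stack_set(maps)
    return fit_lasso_pcr(X, y, lasso_num, seed, groups=groups, mask=maps.mask,
                         affine=maps.affine, training_ids=prov)


# ---------------------------------------------------------------------------
# Leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

def loo_cv(maps: BetaMapSet, lasso_num: int = DEFAULT_LASSO_NUM, seed: int = 0,
           outcomes: dict[str, np.ndarray] | None = None) -> CVResult:
    """LOO-CV prediction-outcome correlation per subject.

    Each subject's per-level maps are predicted by a signature trained on
    all other subjects; the metric is that subject's Pearson correlation
    between predicted and actual levels. ``outcomes`` may override the
    level labels (used by the permutation test); a held-out subject's own
    labels never enter their fold's fit.
    """
    subjects = maps.subjects()
    if len(subjects) < 3:
        raise ValueError("LOO-CV needs at least 3 subjects")
    usable = [s for s in subjects if len(maps.levels(s)) >= 2]
    skipped = [s for s in subjects if s not in usable]
    if skipped:
        logger.warning("skipping %d subject(s) with < 2 levels: %s", len(skipped), skipped)
    rs, preds, acts = [], {}, {}
    for s in usable:
        train = [t for t in usable if t != s]
        X, y, g, _ = _stack_set(maps, train)
        if outcomes is not None:
            y = np.concatenate([outcomes[t] for t in train])
        model = fit_lasso_pcr(X, y, lasso_num, seed, groups=g)
        Xs, ys, _ = maps.subject_stack(s)
        yhat = model.predict(Xs)
        preds[s], acts[s] = yhat, ys
        sd = np.std(yhat)
        rs.append(float(np.corrcoef(yhat, ys)[0, 1]) if sd > 0 else 0.0)
    return CVResult(subject_ids=usable, per_subject_r=np.array(rs),
                    predictions=preds, actuals=acts, skipped=skipped)


def permutation_test(maps: BetaMapSet, n_perm: int = 100, seed: int = 0,
                     lasso_num: int = DEFAULT_LASSO_NUM,
                     observed: CVResult | None = None) -> tuple[float, np.ndarray, float]:
    """Permutation p-value for the LOO-CV mean prediction-outcome r.

    Intensity levels are shuffled *within subject* (respecting the grouped
    design) and LOO-CV is rerun; ``p = (1 + #{perm >= observed}) /
    (n_perm + 1)``. Returns (p, permuted mean r's, observed mean r).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = observed if observed is not None else loo_cv(maps, lasso_num, seed)
    perm_rs = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = {s: rng.permutation(np.array([float(l) for l in maps.levels(s)]))
                    for s in maps.subjects()}
        perm_rs[b] = loo_cv(maps, lasso_num, seed, outcomes=shuffled).mean_r
    p = (1.0 + np.sum(perm_rs >= obs.mean_r)) / (n_perm + 1.0)
    return float(p), perm_rs, obs.mean_r


# ---------------------------------------------------------------------------
# Bootstrap and FDR
# ---------------------------------------------------------------------------

def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def bootstrap_weights(maps: BetaMapSet, n_boot: int = DEFAULT_N_BOOT,
                      q: float = 0.05, seed: int = 0,
                      lasso_num: int = DEFAULT_LASSO_NUM) -> BootstrapResult:
    """Subject-level bootstrap of signature voxel weights with BH-FDR.

    Subjects are resampled with replacement (their maps move jointly), the
    full LASSO-PCR is refit per resample, and each voxel gets
    ``z = bootstrap mean / bootstrap SD`` with a two-tailed normal p-value
    thresholded by Benjamini-Hochberg at ``q``. Degenerate resamples with
    fewer than two distinct subjects are redrawn.
    """
    subjects = maps.subjects()
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, maps.n_voxels))
    for b in range(n_boot):
        while True:
            draw = list(rng.choice(subjects, size=len(subjects), replace=True))
            if len(set(draw)) >= 2:
                break
        X, y, _, _ = _stack_set(maps, draw)
        # each draw position is its own group: duplicates of a subject act
        # as distinct bootstrap units
        g = np.repeat(np.arange(len(draw)), [len(maps.levels(s)) for s in draw])
        W[b] = fit_lasso_pcr(X, y, lasso_num, seed=seed, groups=g).weights
    mean, sd = W.mean(axis=0), W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return BootstrapResult(boot_mean=mean, boot_sd=sd, z=z, p=p,
                           fdr_mask=fdr_bh(p, q), q=q, n_samples=n_boot)
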