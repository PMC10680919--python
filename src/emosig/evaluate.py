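"""Signature application and validation.

A trained signature is applied to new beta maps by pattern expression
(the dot product between the signature's voxel weights and the map,
optionally plus its intercept). Validation tests sensitivity (per-subject
prediction-outcome correlation on the signature's own held-out condition,
one-sample t against 0) and specificity (paired t of own- vs opposite-
condition correlations, with CI and Cohen's d). Cosine similarity
quantifies how dissociated two weight maps are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import BetaMapSet
from .lasso_pcr import PatternModel

logger = logging.getLogger(__name__)


class LeakageError(RuntimeError):
    """Validation maps overlap the signature's training maps."""


@dataclass
class ValidationReport:
    """Per-subject validation correlations and their group-level tests."""

    subject_ids: list[str]
    r_own: np.ndarray
    r_other: np.ndarray
    t_own: float           # one-sample t of r_own vs 0
    p_own: float
    t_paired: float        # paired t of r_own - r_other
    p_paired: float
    ci_paired: tuple[float, float]
    cohens_d: float
    degenerate: bool = False

    @property
    def mean_r_own(self) -> float:
        return float(np.mean(self.r_own))

    @property
    def mean_r_other(self) -> float:
        return float(np.mean(self.r_other))

    @property
    def se_r_own(self) -> float:
        return float(np.std(self.r_own, ddof=1) / np.sqrt(self.r_own.size))


def pattern_expression(model: PatternModel, brain_map: np.ndarray,
                       include_intercept: bool = False,
                       cosine_normalized: bool = False) -> float | np.ndarray:
    """Pattern expression: ``weights . map`` (+ intercept when flagged).

    ``cosine_normalized=True`` divides both vectors by their L2 norms
    first, giving the cosine between signature and map (intercept is then
    ignored).
    """
    m = np.asarray(brain_map, dtype=float)
    if m.shape[-1] != model.weights.size:
        raise ValueError("map geometry does not match model weights")
    w = model.weights
    if cosine_normalized:
        norms = np.linalg.norm(m, axis=-1)
        if np.any(norms == 0) or np.linalg.norm(w) == 0:
            raise ValueError("cosine-normalized expression undefined for zero vectors")
        return (m @ w) / (norms * np.linalg.norm(w))
    out = m @ w
    if include_intercept:
        out = out + model.intercept
    return float(out) if np.ndim(out) == 0 else out


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two maps, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _per_subject_r(model: PatternModel, maps: BetaMapSet) -> tuple[list[str], np.ndarray]:
    subjects = [s for s in maps.subjects() if len(maps.levels(s)) >= 2]
    rs = []
    for s in subjects:
        X, y, _ = maps.subject_stack(s)
        yhat = model.predict(X)
        rs.append(float(np.corrcoef(yhat, y)[0, 1]) if np.std(yhat) > 0 else 0.0)
    return subjects, np.array(rs)


def validate_model(model: PatternModel, own_set: BetaMapSet,
                   other_set: BetaMapSet) -> ValidationReport:
    """Sensitivity and specificity of a signature on held-out conditions.

    Computes each subject's prediction-outcome correlation across levels
    on the signature's own validation set and on the opposite condition's
    set, then a two-tailed one-sample t (own r vs 0) and a two-tailed
    paired t (own vs opposite) with 95% CI and Cohen's d (mean difference
    over SD of differences). Raises :class:`LeakageError` if any
    validation map's provenance id appears among the training maps.
    """
    training_ids = set(model.metadata.get("training_ids", []))
    for m in (own_set, other_set):
        overlap = training_ids & set(m.provenance.values())
        if overlap:
            raise LeakageError(f"validation maps overlap training maps: {sorted(overlap)[:3]}")
    subj_own, r_own = _per_subject_r(model, own_set)
    subj_other, r_other = _per_subject_r(model, other_set)
    common = [s for s in subj_own if s in set(subj_other)]
    r_own = r_own[[subj_own.index(s) for s in common]]
    r_other = r_other[[subj_other.index(s) for s in common]]

    t_own = stats.ttest_1samp(r_own, 0.0, alternative="two-sided")
    diff = r_own - r_other
    sd_diff = float(np.std(diff, ddof=1))
    degenerate = sd_diff == 0.0
    if degenerate:
        logger.warning("paired differences have zero variance; paired test degenerate")
        t_pair_stat, p_pair, ci, d = float("nan"), float("nan"), (float("nan"),) * 2, float("nan")
        if np.allclose(diff, 0.0):
            t_pair_stat, p_pair = 0.0, 1.0
    else:
        t_pair = stats.ttest_rel(r_own, r_other, alternative="two-sided")
        ci_obj = t_pair.confidence_interval(0.95)
        t_pair_stat, p_pair = float(t_pair.statistic), float(t_pair.pvalue)
        ci = (float(ci_obj.low), float(ci_obj.high))
        d = float(np.mean(diff) / sd_diff)
    return ValidationReport(subject_ids=common, r_own=r_own, r_other=r_other,
                            t_own=float(t_own.statistic), p_own=float(t_own.pvalue),
                            t_paired=t_pair_stat, p_paired=p_pair, ci_paired=ci,
                            cohens_d=d, degenerate=degenerate)
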