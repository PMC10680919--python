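"""Signature alignment and empathic accuracy.

Both signatures are applied (dot product + intercept) to each subject's
empathic-accuracy beta maps at the low- and high-accuracy tiers. Within
each tier the two expressions are correlated across subjects; if the
ground-truth and inference representations align more when observers are
accurate, the high-tier correlation exceeds the low-tier one. The tiers
are compared with a two-tailed z-test of the correlation difference
(independent-samples Fisher transform by default; Steiger's dependent-
correlations variant by config). An exploratory voxelwise regression then
maps where low-accuracy brain activity tracks the inference expression
over and above the ground-truth expression (BH-FDR + cluster-extent
pruning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import generate_binary_structure, label

from .glm import BetaMapSet
from .lasso_pcr import PatternModel, fdr_bh

logger = logging.getLogger(__name__)


@dataclass
class AlignmentResult:
    """Low/high-tier expression correlations and their difference test."""

    r_low: float
    r_high: float
    z: float
    p: float
    n_low: int
    n_high: int
    variant: str
    expressions: pd.DataFrame


@dataclass
class DivergenceMap:
    """Voxelwise inference-expression betas controlling for ground truth."""

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    cluster_mask: np.ndarray
    q: float
    k: int


# ---------------------------------------------------------------------------
# Pattern expressions on accuracy maps
# ---------------------------------------------------------------------------

def accuracy_expressions(gt_model: PatternModel, inf_model: PatternModel,
                         ea_maps: BetaMapSet) -> pd.DataFrame:
    """Four expressions per subject: 2 signatures x 2 accuracy tiers.

    Intercepts are included. Subjects missing a tier are excluded with a
    warning. Returns a tidy frame (subject_id, tier, gt_expr, inf_expr).
    """
    rows = []
    for s in ea_maps.subjects():
        tiers = ea_maps.levels(s)
        if not {"low", "high"}.issubset(set(tiers)):
            logger.warning("subject %s missing an accuracy tier; excluded", s)
            continue
        for tier in ("low", "high"):
            m = ea_maps.maps[(s, tier)]
            rows.append({
                "subject_id": s, "tier": tier,
                "gt_expr": float(m @ gt_model.weights + gt_model.intercept),
                "inf_expr": float(m @ inf_model.weights + inf_model.intercept),
            })
    if not rows:
        raise ValueError("no subjects with both accuracy tiers")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation-difference test
# ---------------------------------------------------------------------------

def _steiger_z(r12: float, r34: float, cross: np.ndarray, n: int) -> float:
    """Steiger's z for two dependent, non-overlapping correlations.

    ``cross`` is the 4x4 correlation matrix of the variables (gt_low,
    inf_low, gt_high, inf_high); r12 and r34 are its (0,1) and (2,3)
    entries. Uses the pooled covariance of the Fisher transforms
    (Steiger 1980, case B).
    """
    r13, r14, r23, r24 = cross[0, 2], cross[0, 3], cross[1, 2], cross[1, 3]
    pf = ((r13 - r12 * r23) * (r24 - r23 * r34)
          + (r14 - r13 * r34) * (r23 - r13 * r12)
          + (r13 - r14 * r34) * (r24 - r12 * r14)
          + (r14 - r12 * r24) * (r23 - r24 * r34))
    cov_z = pf / (2.0 * (1.0 - r12 ** 2) * (1.0 - r34 ** 2))
    var = max(1e-12, 2.0 - 2.0 * cov_z) / (n - 3)
    return float((np.arctanh(r34) - np.arctanh(r12)) / np.sqrt(var))


def alignment_test(expressions: pd.DataFrame, variant: str = "fisher") -> AlignmentResult:
    """Compare signature concordance between low and high accuracy tiers.

    ``r_low``/``r_high`` are across-subject Pearson correlations of the
    two signatures' expressions within each tier. The default
    ``"fisher"`` variant treats the tiers as independent samples:
    ``z = (atanh(r_high) - atanh(r_low)) / sqrt(1/(n_low-3) + 1/(n_high-3))``
    with a two-tailed normal p. ``"steiger"`` accounts for the tiers
    sharing subjects via the cross-tier expression correlations.
    """
    low = expressions[expressions.tier == "low"]
    high = expressions[expressions.tier == "high"]
    n_low, n_high = len(low), len(high)
    if min(n_low, n_high) < 10:
        raise ValueError("need at least 10 subjects per tier")
    for name, frame in (("low", low), ("high", high)):
        if frame.gt_expr.std() == 0 or frame.inf_expr.std() == 0:
            raise ValueError(f"constant expressions in {name} tier")
    r_low = float(np.corrcoef(low.gt_expr, low.inf_expr)[0, 1])
    r_high = float(np.corrcoef(high.gt_expr, high.inf_expr)[0, 1])
    if variant == "fisher":
        se = np.sqrt(1.0 / (n_low - 3) + 1.0 / (n_high - 3))
        z = float((np.arctanh(r_high) - np.arctanh(r_low)) / se)
    elif variant == "steiger":
        merged = low.merge(high, on="subject_id", suffixes=("_low", "_high"))
        mat = np.corrcoef(merged[["gt_expr_low", "inf_expr_low",
                                  "gt_expr_high", "inf_expr_high"]].to_numpy(),
                          rowvar=False)
        z = _steiger_z(mat[0, 1], mat[2, 3], mat, len(merged))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p = float(2.0 * stats.norm.sf(abs(z)))
    logger.info("alignment (%s): r_low=%.3f r_high=%.3f z=%.3f p=%.4f",
                variant, r_low, r_high, z, p)
    return AlignmentResult(r_low=r_low, r_high=r_high, z=z, p=p,
                           n_low=n_low, n_high=n_high, variant=variant,
                           expressions=expressions)


# ---------------------------------------------------------------------------
# Exploratory voxelwise divergence regression
# ---------------------------------------------------------------------------

def _prune_clusters(mask_1d: np.ndarray, geometry: np.ndarray | None,
                    k: int) -> np.ndarray:
    """Remove connected components smaller than ``k`` voxels (6-connectivity)."""
    if k <= 1 or geometry is None:
        return mask_1d
    vol = np.zeros(geometry.shape, dtype=bool)
    vol[geometry] = mask_1d
    labeled, n = label(vol, structure=generate_binary_structure(3, 1))
    keep = np.zeros_like(vol)
    for lab in range(1, n + 1):
        comp = labeled == lab
        if comp.sum() >= k:
            keep |= comp
    return keep[geometry]


def divergence_regression(low_maps: BetaMapSet, gt_model: PatternModel,
                          inf_model: PatternModel, q: float = 0.05,
                          k: int = 25, *, predictor: str = "inference") -> DivergenceMap:
    """Voxels tracking one signature's expression, controlling for the other.

    Across subjects' low-accuracy maps, each voxel's value is regressed on
    the inference expression with the ground-truth expression as covariate
    (plus intercept); ``predictor="ground_truth"`` swaps the roles. The
    predictor's t-map is thresholded by BH-FDR at ``q`` and clusters with
    fewer than ``k`` contiguous voxels (6-connectivity) are removed.
    """
    subjects = [s for s in low_maps.subjects() if (s, "low") in low_maps.maps]
    if len(subjects) < 10:
        raise ValueError("need at least 10 subjects")
    M = np.stack([low_maps.maps[(s, "low")] for s in subjects])
    gt_e = M @ gt_model.weights + gt_model.intercept
    inf_e = M @ inf_model.weights + inf_model.intercept
    r = np.corrcoef(gt_e, inf_e)[0, 1]
    if abs(r) > 0.999:
        raise ValueError("expressions are collinear (|r| > 0.999)")
    x1, x2 = (inf_e, gt_e) if predictor == "inference" else (gt_e, inf_e)
    X = np.column_stack([np.ones(len(subjects)), x1, x2])
    n, p_cols = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ M            # p_cols x voxels
    resid = M - X @ betas
    sigma2 = (resid ** 2).sum(axis=0) / (n - p_cols)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas[1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - p_cols)
    fdr = fdr_bh(p, q)
    cluster = _prune_clusters(fdr, low_maps.mask, k)
    return DivergenceMap(beta=betas[1], t=t, p=p, fdr_mask=fdr,
                         cluster_mask=cluster, q=q, k=k)
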