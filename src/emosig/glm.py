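"""Single-trial GLM stage: design construction, OLS, VIF QC, level averaging.

Per subject, boxcar regressors for each (trial, intensity-level) pair are
convolved with a canonical double-gamma haemodynamic response function
(HRF), combined with 36 nuisance regressors and an intercept, and fit to
the voxel x time data by ordinary least squares. Trial regressors whose
variance inflation factor (VIF) exceeds three standard deviations above the
subject's mean are discarded, and surviving trial betas are averaged into
one beta map per intensity level — the features of the decoding stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger(__name__)

N_NUISANCE_DEFAULT = 36


class MulticollinearityError(ValueError):
    """Design columns are linearly dependent."""


@dataclass
class DesignMatrix:
    """GLM design on the TR grid with column provenance.

    Columns are ordered [interest | nuisance | intercept]. Interest columns
    are named ``trial-<id>_level-<lvl>`` so trial betas can later be pooled
    by level.
    """

    frame: pd.DataFrame
    interest: list[str]
    nuisance: list[str]
    has_intercept: bool = True

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_tr(self) -> int:
        return len(self.frame)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))

    def max_interest_correlation(self) -> float:
        """Largest |pairwise correlation| among interest columns (QC audit)."""
        x = self.frame[self.interest].to_numpy(dtype=float)
        if x.shape[1] < 2:
            return 0.0
        c = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(c, 0.0)
        return float(np.nanmax(np.abs(c)))


@dataclass
class BetaMapSet:
    """Masked voxel vectors per (subject, level) sharing one geometry.

    ``condition`` is ``ground_truth``, ``inference`` or ``accuracy``;
    ``level`` keys are 1..5 for the model conditions and ``"low"``/``"high"``
    accuracy tiers for the accuracy condition. ``provenance`` carries a
    unique id per map (used downstream for train/validation leakage checks).
    """

    condition: str
    maps: dict[tuple[str, object], np.ndarray]
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    provenance: dict[tuple[str, object], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = {v.size for v in self.maps.values()}
        if len(sizes) > 1:
            raise ValueError("all maps must share one voxel geometry")
        for key, v in self.maps.items():
            if np.any(~np.isfinite(v)):
                raise ValueError(f"non-finite values inside mask for {key}")
        for key in self.maps:
            self.provenance.setdefault(key, f"{self.condition}:{key[0]}:{key[1]}")

    @property
    def n_voxels(self) -> int:
        return next(iter(self.maps.values())).size

    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.maps}, key=str)

    def levels(self, subject: str) -> list[object]:
        return sorted((l for s, l in self.maps if s == subject), key=str)

    def subject_stack(self, subject: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(maps, numeric levels, provenance ids) for one subject."""
        levels = self.levels(subject)
        X = np.stack([self.maps[(subject, l)] for l in levels])
        y = np.array([float(l) for l in levels])
        prov = [self.provenance[(subject, l)] for l in levels]
        return X, y, prov


# ---------------------------------------------------------------------------
# HRF and convolution
# ---------------------------------------------------------------------------

def canonical_hrf(dt_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt_s``, peak-normalized to 1.

    Positive lobe peaking at 6 s, undershoot peaking at 16 s with ratio
    1/6, 32 s support. The kernel is 0 at t = 0 and changes sign exactly
    once (positive response followed by the undershoot).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    from scipy.stats import gamma

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    # gamma pdf with scale 1 peaks at shape - 1
    h = gamma.pdf(t, a=7.0) - gamma.pdf(t, a=17.0) / 6.0
    return h / h.max()


def convolve_design(regressors: pd.DataFrame | np.ndarray, kernel: np.ndarray) -> pd.DataFrame | np.ndarray:
    """Causal convolution of each column with the kernel, truncated to length."""
    is_frame = isinstance(regressors, pd.DataFrame)
    x = regressors.to_numpy(dtype=float) if is_frame else np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    out = np.column_stack([np.convolve(x[:, j], kernel)[:n] for j in range(x.shape[1])])
    if is_frame:
        return pd.DataFrame(out, columns=regressors.columns, index=regressors.index)
    return out if np.asarray(regressors).ndim > 1 else out[:, 0]


# ---------------------------------------------------------------------------
# Design assembly and OLS
# ---------------------------------------------------------------------------

def assemble_design(
    interest: pd.DataFrame,
    nuisance: np.ndarray | pd.DataFrame | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Stack [interest | nuisance | intercept] and verify interest rank."""
    parts = [interest]
    nuis_names: list[str] = []
    if nuisance is not None:
        nuis = pd.DataFrame(
            np.asarray(nuisance, dtype=float),
            columns=[f"nuisance-{j:02d}" for j in range(np.asarray(nuisance).shape[1])]
            if not isinstance(nuisance, pd.DataFrame) else nuisance.columns,
            index=interest.index,
        )
        nuis_names = list(nuis.columns)
        if len(nuis) != len(interest):
            raise ValueError("interest and nuisance row counts differ")
        parts.append(nuis)
    if intercept:
        parts.append(pd.DataFrame({"intercept": np.ones(len(interest))}, index=interest.index))
    frame = pd.concat(parts, axis=1)
    if frame.columns.duplicated().any():
        raise MulticollinearityError("duplicate column names in design")
    x_int = interest.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x_int) < x_int.shape[1]:
        raise MulticollinearityError("interest columns are rank deficient")
    dm = DesignMatrix(frame=frame, interest=list(interest.columns), nuisance=nuis_names,
                      has_intercept=intercept)
    logger.info("design assembled: %d rows, %d columns, rank %d",
                dm.n_tr, len(dm.columns), dm.rank)
    return dm


def fit_ols(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS of ``Y`` (voxel x time) on the design.

    Returns ``(betas, sigma2)`` with betas voxel x column and sigma2 the
    per-voxel residual variance (denominator n - p).
    """
    x = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = x.shape
    if Y.shape[1] != n:
        raise ValueError("Y time dimension must match design rows")
    if n <= p:
        raise ValueError("need more time points than design columns")
    if np.linalg.matrix_rank(x) < p:
        raise MulticollinearityError("design matrix is singular")
    betas, _, _, _ = np.linalg.lstsq(x, Y.T, rcond=None)
    resid = Y.T - x @ betas
    sigma2 = (resid ** 2).sum(axis=0) / (n - p)
    return betas.T, sigma2


# ---------------------------------------------------------------------------
# VIF quality control
# ---------------------------------------------------------------------------

def vif(X: DesignMatrix, columns_of_interest: list[str] | None = None) -> pd.Series:
    """VIF_j = 1/(1 - R^2_j) for each interest column against the full design."""
    cols = columns_of_interest if columns_of_interest is not None else X.interest
    x = X.values
    idx = [X.columns.index(c) for c in cols]
    out = {}
    with np.errstate(divide="ignore"):
        for c, j in zip(cols, idx):
            try:
                v = variance_inflation_factor(x, j)
            except (np.linalg.LinAlgError, ZeroDivisionError):
                v = np.inf
            out[c] = np.inf if not np.isfinite(v) or v > 1e12 else float(v)
    return pd.Series(out, name="vif")


def drop_high_vif_trials(vifs: pd.Series) -> tuple[list[str], list[str]]:
    """Split one subject's interest columns into (retained, removed).

    A column is removed when its VIF exceeds the mean + 3 SD of the
    subject's *other* columns (leave-one-out, so a single extreme outlier
    cannot hide by inflating its own threshold). With all-equal VIFs
    nothing is removed; infinite VIFs are always removed.
    """
    finite = vifs[np.isfinite(vifs)]
    removed = list(vifs.index[~np.isfinite(vifs)])
    if len(finite) > 1:
        vals = finite.to_numpy(dtype=float)
        for name, v in finite.items():
            others = vals[finite.index != name]
            if others.size < 2:
                continue
            if v > others.mean() + 3 * others.std(ddof=1):
                removed.append(name)
    retained = [c for c in vifs.index if c not in removed]
    if removed:
        logger.info("VIF QC removed %d of %d trial regressors: %s",
                    len(removed), len(vifs), removed)
    return retained, removed


# ---------------------------------------------------------------------------
# Level averaging
# ---------------------------------------------------------------------------

def parse_level(column: str) -> object:
    """Extract the level token from a ``trial-<id>_level-<lvl>`` column name."""
    token = column.rsplit("_level-", 1)[1]
    return int(token) if token.isdigit() else token


def average_level_betas(
    betas: np.ndarray,
    design: DesignMatrix,
    retained: list[str] | None = None,
) -> dict[object, np.ndarray]:
    """Average retained trial betas into one map per intensity level.

    ``betas`` is voxel x column as returned by :func:`fit_ols`. Returns a
    dict ``level -> voxel vector``; levels with no retained trials are
    simply absent (flagged by the caller).
    """
    cols = retained if retained is not None else design.interest
    if not cols:
        raise ValueError("no retained trial columns")
    by_level: dict[object, list[int]] = {}
    for c in cols:
        by_level.setdefault(parse_level(c), []).append(design.columns.index(c))
    return {lvl: betas[:, idx].mean(axis=1) for lvl, idx in sorted(
        by_level.items(), key=lambda kv: str(kv[0]))}
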