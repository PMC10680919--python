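"""Continuous affect-rating preprocessing.

Targets rate the felt emotional intensity of their own story videos and
observers rate what they believe the target felt, both on a 0-100 bipolar
valence scale sampled every 0.5 s. This module turns those raw streams into
the inputs of the single-trial GLM stage:

1. down-sample to the fMRI repetition time (TR, 2 s),
2. range-normalize to [0, 1] (per trial for targets, across all trials for
   observers),
3. fold out valence into 5 levels of emotional intensity, symmetric about
   the scale midpoint,
4. derive moment-by-moment empathic-accuracy (EA) levels from the
   observer-target difference,
5. expand level series into per-(trial, level) boxcar regressors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_SAMPLING_S = 0.5
SLIDER_STEP = 12.0
N_LEVELS = 5

#: Valence-independent intensity bins on the 0-100 scale. Each row is
#: (low, high, level) with closed/half-open conventions chosen so every
#: boundary value falls in the *less extreme* level. The table is symmetric
#: about 50.5 (the reflection v -> 101 - v maps each bin onto itself).
INTENSITY_BINS = (
    (41.0, 60.0, 1),     # [41, 60] -> 1
    (31.0, 41.0, 2),     # [31, 41) and (60, 70]
    (60.0, 70.0, 2),
    (21.0, 31.0, 3),     # [21, 31) and (70, 80]
    (70.0, 80.0, 3),
    (11.0, 21.0, 4),     # [11, 21) and (80, 90]
    (80.0, 90.0, 4),
    (0.0, 11.0, 5),      # [0, 11) and (90, 100]
    (90.0, 100.0, 5),
)


class DegenerateSeriesError(ValueError):
    """A rating series is constant and cannot be range-normalized."""


@dataclass
class RatingSeries:
    """Timestamped 0-100 ratings for one person on one trial.

    ``time_s`` must be strictly increasing; ``rating`` within [0, 100].
    ``role`` is "target" (self-rating; the paradigm's ground truth) or
    "observer" (inference while watching). ``modality`` partitions trials
    into training (audiovisual) and validation (audio, visual) conditions.
    """

    subject_id: str
    role: str
    trial_id: str
    modality: str
    time_s: np.ndarray
    rating: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.rating = np.asarray(self.rating, dtype=float)
        if self.time_s.shape != self.rating.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and rating must be 1-D arrays of equal length")
        if self.time_s.size == 0:
            raise ValueError("empty rating series")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        lo, hi = (0.0, 1.0) if self.normalized else (0.0, 100.0)
        if self.rating.min() < lo - 1e-9 or self.rating.max() > hi + 1e-9:
            raise ValueError(f"ratings must lie in [{lo}, {hi}]")

    @property
    def duration_s(self) -> float:
        dt = self.time_s[1] - self.time_s[0] if self.time_s.size > 1 else RAW_SAMPLING_S
        return float(self.time_s.size * dt)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class IntensitySeries:
    """Per-TR valence-independent intensity levels (1..5) for one trial."""

    subject_id: str
    trial_id: str
    tr_index: np.ndarray
    level: np.ndarray
    kind: str  # ground_truth | inference

    def __post_init__(self) -> None:
        self.tr_index = np.asarray(self.tr_index, dtype=int)
        self.level = np.asarray(self.level, dtype=int)
        if not np.all((self.level >= 1) & (self.level <= N_LEVELS)):
            raise ValueError("levels must be integers 1..5")


@dataclass
class AccuracySeries:
    """Per-TR empathic-accuracy levels with the signed observer-target gap.

    ``ea_level`` is 5 where the normalized observer and target ratings
    coincide (most accurate) and 1 at the maximal difference in either
    direction. The signed difference ``d = obs - gt`` is retained because
    the accuracy measure itself is not valence independent.
    """

    subject_id: str
    trial_id: str
    tr_index: np.ndarray
    ea_level: np.ndarray
    signed_d: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tr_index = np.asarray(self.tr_index, dtype=int)
        self.ea_level = np.asarray(self.ea_level, dtype=int)
        if not np.all((self.ea_level >= 1) & (self.ea_level <= N_LEVELS)):
            raise ValueError("ea_level must be integers 1..5")


# ---------------------------------------------------------------------------
# 1. TR down-sampling
# ---------------------------------------------------------------------------

def downsample_to_tr(
    series: RatingSeries, tr_s: float = 2.0, aggregator: str = "mean"
) -> RatingSeries:
    """Down-sample a 0.5 s rating stream to the TR grid.

    Each TR value aggregates the raw samples falling in its window; the
    default aggregator is the mean (``"last"`` keeps the final sample of
    each window). Output length is ``floor(duration / tr_s)``; trailing
    samples not filling a whole TR are dropped.
    """
    if len(series) == 0:
        raise ValueError("empty rating series")
    if tr_s <= 0 or abs(tr_s / RAW_SAMPLING_S - round(tr_s / RAW_SAMPLING_S)) > 1e-9:
        raise ValueError("tr_s must be a positive multiple of 0.5 s")
    per_tr = int(round(tr_s / RAW_SAMPLING_S))
    n_tr = len(series) // per_tr
    if n_tr == 0:
        raise ValueError("series shorter than one TR")
    block = series.rating[: n_tr * per_tr].reshape(n_tr, per_tr)
    if aggregator == "mean":
        values = block.mean(axis=1)
    elif aggregator == "last":
        values = block[:, -1]
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return replace(series, time_s=np.arange(n_tr) * tr_s, rating=values)


# ---------------------------------------------------------------------------
# 2. Range normalization (feature scaling)
# ---------------------------------------------------------------------------

def range_normalize(
    series: RatingSeries | list[RatingSeries], scope: str = "per_trial"
) -> RatingSeries | list[RatingSeries]:
    """Min-max normalize ratings to [0, 1].

    ``scope="per_trial"`` (targets) normalizes each series by its own
    min/max; ``scope="across_trials"`` (observers) pools min/max over every
    series passed, so a single trial's maximum need not reach 1. Constant
    input (max == min) raises :class:`DegenerateSeriesError` — such trials
    are excluded rather than imputed.
    """
    single = isinstance(series, RatingSeries)
    items = [series] if single else list(series)
    if not items:
        raise ValueError("no series to normalize")

    def _apply(s: RatingSeries, lo: float, hi: float) -> RatingSeries:
        if hi <= lo:
            raise DegenerateSeriesError(
                f"constant ratings for subject {s.subject_id} trial {s.trial_id}: "
                "cannot range-normalize"
            )
        return replace(s, rating=(s.rating - lo) / (hi - lo), normalized=True)

    if scope == "per_trial":
        out = [_apply(s, s.rating.min(), s.rating.max()) for s in items]
    elif scope == "across_trials":
        lo = min(s.rating.min() for s in items)
        hi = max(s.rating.max() for s in items)
        out = [_apply(s, lo, hi) for s in items]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return out[0] if single else out


def normalize_or_exclude(
    series: list[RatingSeries], scope: str
) -> tuple[list[RatingSeries], list[RatingSeries]]:
    """Normalize a batch, excluding (with a warning) constant series."""
    kept: list[RatingSeries] = []
    excluded: list[RatingSeries] = []
    if scope == "across_trials":
        try:
            return list(range_normalize(series, scope)), []
        except DegenerateSeriesError:
            excluded = list(series)
            warnings.warn("constant across-trial ratings excluded", stacklevel=2)
            logger.warning("excluded %d constant-rating series", len(excluded))
            return [], excluded
    for s in series:
        try:
            kept.append(range_normalize(s, scope))
        except DegenerateSeriesError:
            excluded.append(s)
            logger.warning(
                "excluded constant-rating trial %s of subject %s", s.trial_id, s.subject_id
            )
    if excluded:
        warnings.warn(f"{len(excluded)} constant-rating trial(s) excluded", stacklevel=2)
    return kept, excluded


# ---------------------------------------------------------------------------
# 3. Valence-independent intensity levels
# ---------------------------------------------------------------------------

def to_intensity_level(normalized: np.ndarray | float) -> np.ndarray | int:
    """Map normalized ratings in [0, 1] to intensity levels 1..5.

    The rating is rescaled to the 0-100 scale and binned with the printed
    table: {41-60}->1, {31-40, 61-70}->2, {21-30, 71-80}->3,
    {11-20, 81-90}->4, {0-10, 91-100}->5. Level 5 is the highest intensity;
    the map folds out valence (it is invariant under v -> 101 - v).
    """
    x = np.asarray(normalized, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("normalized ratings must lie in [0, 1]")
    v = np.clip(x * 100.0, 0.0, 100.0)
    out = np.zeros(v.shape, dtype=int)
    # closed central bin, then half-open shells; boundaries go to the less
    # extreme level because the central bin is applied first
    out[(v >= 41.0) & (v <= 60.0)] = 1
    shell = out == 0
    for lo, hi, lvl in INTENSITY_BINS[1:]:
        if lvl == 5 and hi == 100.0:
            sel = shell & (v > lo) & (v <= hi + 1e-12)
        elif lo == 0.0:
            sel = shell & (v >= lo) & (v < hi)
        elif hi > 50.0:
            sel = shell & (v > lo) & (v <= hi)
        else:
            sel = shell & (v >= lo) & (v < hi)
        out[sel] = lvl
    assert np.all(out >= 1)
    return int(out[0]) if scalar else out


def intensity_series(series: RatingSeries, kind: str) -> IntensitySeries:
    """Convert a normalized, TR-gridded rating series to intensity levels."""
    if not series.normalized:
        raise ValueError("series must be range-normalized first")
    levels = to_intensity_level(series.rating)
    return IntensitySeries(
        subject_id=series.subject_id,
        trial_id=series.trial_id,
        tr_index=np.arange(len(series)),
        level=levels,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# 4. Empathic accuracy
# ---------------------------------------------------------------------------

def empathic_accuracy(
    gt_norm: RatingSeries, obs_norm: RatingSeries
) -> AccuracySeries:
    """Derive empathic-accuracy levels from aligned normalized series.

    ``d = observer - ground_truth`` per TR; ``|d|`` is cut into 5
    equal-width bins of [0, 1], mapped so that no difference gives level 5
    and the maximal difference in either direction gives level 1.
    """
    if len(gt_norm) != len(obs_norm) or not np.allclose(gt_norm.time_s, obs_norm.time_s):
        raise ValueError("ground-truth and observer series must share the TR grid")
    if not (gt_norm.normalized and obs_norm.normalized):
        raise ValueError("series must be range-normalized")
    d = obs_norm.rating - gt_norm.rating
    a = np.abs(d)
    # bins [0,.2]->5 (.2,.4]->4 (.4,.6]->3 (.6,.8]->2 (.8,1]->1
    ea = 5 - np.digitize(a, [0.2, 0.4, 0.6, 0.8], right=True)
    return AccuracySeries(
        subject_id=obs_norm.subject_id,
        trial_id=obs_norm.trial_id,
        tr_index=np.arange(len(d)),
        ea_level=ea,
        signed_d=d,
    )


# ---------------------------------------------------------------------------
# 5. Per-(trial, level) boxcar regressors
# ---------------------------------------------------------------------------

def build_level_regressors(
    series: list[IntensitySeries] | list[AccuracySeries],
    trial_offsets_tr: dict[str, int] | None = None,
    n_tr_total: int | None = None,
) -> pd.DataFrame:
    """Expand level series into per-(trial, level) indicator columns.

    One column per (trial, level) pair that actually occurs — the column
    count therefore varies by subject. Within a trial the columns are
    disjoint in time and sum to the trial's on-screen indicator.
    ``trial_offsets_tr`` places each trial on a concatenated run grid; by
    default trials are laid out back to back.
    """
    if not series:
        raise ValueError("no intensity series given")
    if trial_offsets_tr is None:
        trial_offsets_tr = {}
        cursor = 0
        for s in series:
            trial_offsets_tr[s.trial_id] = cursor
            cursor += s.tr_index.size
        total = cursor
    else:
        total = n_tr_total if n_tr_total is not None else max(
            trial_offsets_tr[s.trial_id] + s.tr_index.size for s in series
        )
    cols: dict[str, np.ndarray] = {}
    for s in series:
        levels = s.level if isinstance(s, IntensitySeries) else s.ea_level
        off = trial_offsets_tr[s.trial_id]
        for lvl in np.unique(levels):
            col = np.zeros(total)
            col[off + s.tr_index[levels == lvl]] = 1.0
            cols[f"trial-{s.trial_id}_level-{lvl}"] = col
    return pd.DataFrame(cols)
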