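"""Synthetic study generator with known ground truth.

Emulates the statistical structure of the socioemotional fMRI paradigm —
targets telling emotional stories and observers inferring their feelings —
without any real data: continuous 0-100 slider ratings on a 0.5 s grid,
per-subject per-intensity-level beta maps built from two latent voxel
patterns (one for the signal's "ground truth" intensity, one for the
observer's inference) with a controllable cosine similarity, level-
proportional signal, subject random effects and Gaussian voxel noise, plus
nuisance regressors and 4-D voxel x time data for the GLM stage.

Every generator takes an explicit seed and is byte-reproducible. The
defaults mirror the study conditions: 100 observers, 5 intensity levels,
a multimodal (audiovisual) training condition and unimodal (audio, visual)
validation conditions, and a pattern cosine of 0.29.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .glm import BetaMapSet, DesignMatrix
from .ratings import RAW_SAMPLING_S, SLIDER_STEP, RatingSeries

#: default voxel geometry: a 10 x 10 x 20 solid box inside a 12 x 12 x 22
#: rectangular volume (2000 in-mask voxels)
DEFAULT_GRID = (12, 12, 22)
DEFAULT_BOX = ((1, 11), (1, 11), (1, 21))

MODALITIES = ("audiovisual", "audio", "visual")
TRAIN_MODALITY = "audiovisual"
VALIDATION_MODALITIES = ("audio", "visual")


def default_mask(grid: tuple[int, int, int] = DEFAULT_GRID,
                 box=DEFAULT_BOX) -> np.ndarray:
    mask = np.zeros(grid, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    mask[x0:x1, y0:y1, z0:z1] = True
    return mask


def mask_for(n_voxels: int) -> np.ndarray:
    """A mask matching ``n_voxels``: the standard box for 2000, a flat strip otherwise."""
    if n_voxels == int(np.sum(default_mask())):
        return default_mask()
    return np.ones((1, 1, n_voxels), dtype=bool)


@dataclass
class SyntheticTruth:
    """Latent structure of a synthetic study.

    Two unit-norm voxel patterns carry the ground-truth and inference
    signal; their cosine similarity defaults to 0.29, the dissociation
    observed between the two trained signatures. Signal grows linearly
    with intensity level (``effect_* x level``), subjects get a random
    voxelwise offset map (SD ``subject_sd``), and iid Gaussian noise of SD
    ``noise_sd`` is added per voxel. ``mixing`` leaks a fraction of the
    opposite pattern into each condition (both processes co-occur in a
    real brain).
    """

    n_subjects: int = 100
    n_voxels: int = 2000
    pattern_cosine: float = 0.29
    effect_gt: float = 1.0
    effect_inf: float = 1.0
    subject_sd: float = 1.0
    noise_sd: float = 1.1
    mixing: float = 0.3
    seed: int = 0
    pattern_gt: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    pattern_inf: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if min(self.subject_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.pattern_gt is None or self.pattern_inf is None:
            self.pattern_gt, self.pattern_inf = gen_patterns(
                self.n_voxels, self.pattern_cosine, self.seed
            )
        realized = float(self.pattern_gt @ self.pattern_inf)
        if abs(realized - self.pattern_cosine) > 0.02:
            raise ValueError("realized pattern cosine deviates from request")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_voxels": self.n_voxels,
            "pattern_cosine": self.pattern_cosine,
            "effect_gt": self.effect_gt,
            "effect_inf": self.effect_inf,
            "subject_sd": self.subject_sd,
            "noise_sd": self.noise_sd,
            "mixing": self.mixing,
            "seed": self.seed,
        }


@dataclass
class SyntheticStudy:
    """A complete simulated study: ratings, trial table, beta maps, truth."""

    truth: SyntheticTruth
    trials: pd.DataFrame
    ratings: list[RatingSeries]
    beta_maps: dict[tuple[str, str], BetaMapSet]  # (condition, modality_group)
    observer_accuracy: dict[str, float]


# ---------------------------------------------------------------------------
# Rating streams
# ---------------------------------------------------------------------------

def _caterpillar_walk(n: int, rng: np.random.Generator,
                      persistence: float = 0.8,
                      step: float = SLIDER_STEP) -> np.ndarray:
    """Bounded piecewise-constant walk on [0, 100], steps in {0, +-step}.

    A "lazy caterpillar": the move direction (left / stay / right) is
    repeated with probability ``persistence``, giving slider-like
    autocorrelation. Moves that would leave [0, 100] are dropped (the
    slider sits at its end stop), so consecutive differences are always
    multiples of the button step.
    """
    values = np.empty(n)
    values[0] = 50.0
    move = rng.integers(-1, 2)
    for i in range(1, n):
        if rng.random() >= persistence:
            move = rng.integers(-1, 2)
        proposal = values[i - 1] + move * step
        values[i] = proposal if 0.0 <= proposal <= 100.0 else values[i - 1]
    return values


def gen_target_ratings(duration_s: float, seed: int, *,
                       subject_id: str = "target", trial_id: str = "trial",
                       modality: str = TRAIN_MODALITY,
                       persistence: float = 0.8) -> RatingSeries:
    """A target's self-rating stream: 0.5 s samples, 12-pt slider steps."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / RAW_SAMPLING_S))
    values = _caterpillar_walk(n, rng, persistence)
    return RatingSeries(subject_id=subject_id, role="target", trial_id=trial_id,
                        modality=modality, time_s=np.arange(n) * RAW_SAMPLING_S,
                        rating=values)


def gen_observer_ratings(target: RatingSeries, accuracy: float,
                         lag_s: float = 1.0, noise_sd: float = 6.0,
                         seed: int = 0, *, subject_id: str = "observer") -> RatingSeries:
    """An observer's inference stream derived from the target's stream.

    The observer tracks an ``accuracy``-weighted, lagged copy of the target
    blended with an independent walk of their own, plus smoothed Gaussian
    noise, re-quantized to the 12-pt slider grid and clipped to [0, 100].
    ``accuracy=1, lag=0, noise_sd=0`` reproduces the target exactly;
    ``accuracy=0`` is independent of it.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if lag_s < 0:
        raise ValueError("lag_s must be >= 0")
    n = len(target)
    lag = int(round(lag_s / RAW_SAMPLING_S))
    if lag >= n:
        raise ValueError("lag exceeds trial duration")
    rng = np.random.default_rng(seed)
    lagged = np.concatenate([np.full(lag, target.rating[0]), target.rating[: n - lag]])
    own = _caterpillar_walk(n, rng)
    raw = accuracy * lagged + (1.0 - accuracy) * own
    if noise_sd > 0:
        raw = raw + gaussian_filter1d(rng.normal(0.0, noise_sd, n), sigma=2.0)
    # snap back to reachable slider positions (50 + 12k), then clip
    quantized = 50.0 + SLIDER_STEP * np.round((raw - 50.0) / SLIDER_STEP)
    return RatingSeries(subject_id=subject_id, role="observer",
                        trial_id=target.trial_id, modality=target.modality,
                        time_s=target.time_s.copy(),
                        rating=np.clip(quantized, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Latent patterns and beta maps
# ---------------------------------------------------------------------------

def gen_patterns(n_voxels: int, pattern_cosine: float,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-norm voxel patterns with an exact requested cosine.

    The second pattern is ``cos(theta) * first + sin(theta) * residual``
    with the residual orthonormalized against the first, so the realized
    cosine matches the request to machine precision.
    """
    if n_voxels < 10:
        raise ValueError("need at least 10 voxels")
    if not -1.0 <= pattern_cosine <= 1.0:
        raise ValueError("pattern_cosine must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n_voxels)
    u /= np.linalg.norm(u)
    r = rng.standard_normal(n_voxels)
    r -= (r @ u) * u
    r /= np.linalg.norm(r)
    v = pattern_cosine * u + np.sqrt(max(0.0, 1.0 - pattern_cosine ** 2)) * r
    return u, v


def gen_beta_maps(truth: SyntheticTruth, *, condition: str = "ground_truth",
                  levels: range | list[int] = range(1, 6),
                  effect_scale: float = 1.0, modality: str = TRAIN_MODALITY,
                  seed: int | None = None,
                  mask: np.ndarray | None = None) -> BetaMapSet:
    """Per-subject per-level beta maps with level-proportional signal.

    ``map(s, L) = L*e_own*own_pattern + mixing*L*e_other*other_pattern
    + subject_offset(s) + noise``; the ground-truth and inference
    conditions swap which pattern is "own". ``effect_scale`` (< 1 for the
    unimodal validation conditions) scales both effects.
    """
    if condition == "ground_truth":
        own, e_own = truth.pattern_gt, truth.effect_gt
        other, e_other = truth.pattern_inf, truth.effect_inf
    elif condition == "inference":
        own, e_own = truth.pattern_inf, truth.effect_inf
        other, e_other = truth.pattern_gt, truth.effect_gt
    else:
        raise ValueError(f"unknown model condition {condition!r}")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    maps: dict[tuple[str, object], np.ndarray] = {}
    prov: dict[tuple[str, object], str] = {}
    for s in range(truth.n_subjects):
        sid = f"sub-{s:03d}"
        offset = truth.subject_sd * rng.standard_normal(truth.n_voxels)
        for lvl in levels:
            signal = effect_scale * lvl * (e_own * own + truth.mixing * e_other * other)
            noise = truth.noise_sd * rng.standard_normal(truth.n_voxels)
            maps[(sid, int(lvl))] = signal + offset + noise
            prov[(sid, int(lvl))] = f"{condition}:{modality}:{sid}:{lvl}"
    return BetaMapSet(condition=condition, maps=maps,
                      mask=mask_for(truth.n_voxels) if mask is None else mask,
                      affine=np.eye(4), provenance=prov)


def gen_accuracy_maps(truth: SyntheticTruth, *, concordance_low: float = -0.3,
                      concordance_high: float = 0.35, amplitude: float = 3.0,
                      amplitude_sd: float = 3.0, modality: str = TRAIN_MODALITY,
                      seed: int | None = None,
                      mask: np.ndarray | None = None) -> BetaMapSet:
    """Empathic-accuracy condition maps at two accuracy tiers.

    Each subject's map mixes the two latent patterns with bivariate-normal
    coefficients whose correlation equals the tier's concordance: under
    high accuracy the brain expresses ground truth and inference
    concordantly, under low accuracy discordantly. Because the patterns
    themselves overlap (cosine 0.29), the correlation between the two
    signatures' pattern *expressions* sits above the coefficient
    concordance; the defaults place it near 0.3 (low tier) and 0.65
    (high tier) for well-estimated signatures at study scale.
    """
    for c in (concordance_low, concordance_high):
        if not -1.0 <= c <= 1.0:
            raise ValueError("concordance must lie in [-1, 1]")
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    maps: dict[tuple[str, object], np.ndarray] = {}
    prov: dict[tuple[str, object], str] = {}
    for s in range(truth.n_subjects):
        sid = f"sub-{s:03d}"
        offset = truth.subject_sd * rng.standard_normal(truth.n_voxels)
        for tier, conc in (("low", concordance_low), ("high", concordance_high)):
            x, y_ind = rng.standard_normal(2)
            c_gt = amplitude + amplitude_sd * x
            c_inf = amplitude + amplitude_sd * (conc * x + np.sqrt(1 - conc ** 2) * y_ind)
            noise = truth.noise_sd * rng.standard_normal(truth.n_voxels)
            maps[(sid, tier)] = (c_gt * truth.effect_gt * truth.pattern_gt
                                 + c_inf * truth.effect_inf * truth.pattern_inf
                                 + offset + noise)
            prov[(sid, tier)] = f"accuracy:{modality}:{sid}:{tier}"
    return BetaMapSet(condition="accuracy", maps=maps,
                      mask=mask_for(truth.n_voxels) if mask is None else mask,
                      affine=np.eye(4), provenance=prov)


# ---------------------------------------------------------------------------
# GLM-stage inputs
# ---------------------------------------------------------------------------

def gen_nuisance(n_tr: int, n_regressors: int = 36, seed: int = 0) -> np.ndarray:
    """Nuisance regressor matrix: smoothed noise plus one-hot spike columns.

    Emulates the roles of CSF/white-matter and motion regressors with their
    derivatives (smooth, autocorrelated processes) and motion-outlier
    spikes (one-hot indicator columns).
    """
    if n_tr <= n_regressors:
        raise ValueError("need more time points than nuisance regressors")
    rng = np.random.default_rng(seed)
    n_spikes = max(1, n_regressors // 12)
    n_smooth = n_regressors - n_spikes
    smooth = gaussian_filter1d(rng.standard_normal((n_tr, n_smooth)), sigma=3.0, axis=0)
    smooth = (smooth - smooth.mean(axis=0)) / smooth.std(axis=0)
    spikes = np.zeros((n_tr, n_spikes))
    spikes[rng.choice(n_tr, size=n_spikes, replace=False), np.arange(n_spikes)] = 1.0
    return np.column_stack([smooth, spikes])


def true_betas_for_design(design: DesignMatrix, truth: SyntheticTruth, *,
                          condition: str = "ground_truth", seed: int = 0,
                          nuisance_beta_sd: float = 0.1) -> np.ndarray:
    """Voxel x column coefficient matrix consistent with the latent truth.

    Interest columns named ``..._level-L`` get ``L * effect * pattern``
    rows (plus mixing); nuisance and intercept columns get small random
    coefficients.
    """
    from .glm import parse_level

    own, other = ((truth.pattern_gt, truth.pattern_inf)
                  if condition == "ground_truth"
                  else (truth.pattern_inf, truth.pattern_gt))
    e_own = truth.effect_gt if condition == "ground_truth" else truth.effect_inf
    e_other = truth.effect_inf if condition == "ground_truth" else truth.effect_gt
    rng = np.random.default_rng(seed)
    B = np.zeros((truth.n_voxels, len(design.columns)))
    for j, col in enumerate(design.columns):
        if col in design.interest:
            lvl = float(parse_level(col))
            B[:, j] = lvl * (e_own * own + truth.mixing * e_other * other)
        else:
            B[:, j] = nuisance_beta_sd * rng.standard_normal(truth.n_voxels)
    return B


def gen_voxel_timeseries(design: DesignMatrix, truth: SyntheticTruth, seed: int = 0,
                         *, condition: str = "ground_truth") -> tuple[np.ndarray, np.ndarray]:
    """4-D-equivalent voxel x time data ``Y = X B + E`` for the GLM stage.

    Returns ``(Y, B_true)`` with Y voxel x time and B_true voxel x column.
    ``E`` is iid Gaussian with the truth's ``noise_sd``.
    """
    B = true_betas_for_design(design, truth, condition=condition, seed=seed)
    X = design.values
    if X.shape[1] != B.shape[1]:
        raise ValueError("design/coefficient dimension mismatch")
    rng = np.random.default_rng(seed + 1)
    E = truth.noise_sd * rng.standard_normal((truth.n_voxels, X.shape[0]))
    return (X @ B.T).T + E, B


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------

def make_trial_table(seed: int = 0, *, n_audiovisual: int = 8,
                     n_audio: int = 4, n_visual: int = 4) -> pd.DataFrame:
    """Trial table: 8 audiovisual training trials + unimodal validation."""
    rng = np.random.default_rng(seed)
    rows = []
    counts = {"audiovisual": n_audiovisual, "audio": n_audio, "visual": n_visual}
    i = 0
    for modality in MODALITIES:
        for _ in range(counts[modality]):
            duration = float(rng.integers(30, 91) * 2)  # 60-180 s, whole TRs
            rows.append({"trial_id": f"trial-{i:02d}", "modality": modality,
                         "duration_s": duration})
            i += 1
    return pd.DataFrame(rows)


def simulate_study(n_subjects: int = 100, n_voxels: int = 2000, seed: int = 0,
                   *, truth: SyntheticTruth | None = None,
                   validation_effect_scale: float = 0.6,
                   concordance_low: float = -0.3,
                   concordance_high: float = 0.35,
                   n_observer_ratings: int | None = None) -> SyntheticStudy:
    """Generate a full synthetic study.

    Produces the trial table, target and observer rating streams, training
    (audiovisual) and validation (audio+visual pooled) beta-map sets for
    both model conditions, and low/high empathic-accuracy maps for both
    trial groups. Validation-condition signal is scaled down (unimodal
    stimuli carry less of the multimodal signal).
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(12) % (2 ** 31)]
    if truth is None:
        truth = SyntheticTruth(n_subjects=n_subjects, n_voxels=n_voxels, seed=seeds[0])
    trials = make_trial_table(seeds[1])
    rng = np.random.default_rng(seeds[2])

    ratings: list[RatingSeries] = []
    targets: dict[str, RatingSeries] = {}
    for i, row in trials.iterrows():
        t = gen_target_ratings(row.duration_s, seeds[3] + i,
                               subject_id=f"target-{i:02d}", trial_id=row.trial_id,
                               modality=row.modality)
        targets[row.trial_id] = t
        ratings.append(t)
    accuracy = {f"sub-{s:03d}": float(rng.uniform(0.3, 0.9)) for s in range(n_subjects)}
    n_raters = n_subjects if n_observer_ratings is None else min(n_observer_ratings, n_subjects)
    for s in range(n_raters):
        sid = f"sub-{s:03d}"
        for i, row in trials.iterrows():
            ratings.append(gen_observer_ratings(
                targets[row.trial_id], accuracy[sid], lag_s=1.0, noise_sd=6.0,
                seed=seeds[4] + 1000 * s + i, subject_id=sid))

    mask = mask_for(truth.n_voxels)
    beta_maps = {
        ("ground_truth", "train"): gen_beta_maps(
            truth, condition="ground_truth", seed=seeds[5], mask=mask),
        ("inference", "train"): gen_beta_maps(
            truth, condition="inference", seed=seeds[6], mask=mask),
        ("ground_truth", "validation"): gen_beta_maps(
            truth, condition="ground_truth", effect_scale=validation_effect_scale,
            modality="audio+visual", seed=seeds[7], mask=mask),
        ("inference", "validation"): gen_beta_maps(
            truth, condition="inference", effect_scale=validation_effect_scale,
            modality="audio+visual", seed=seeds[8], mask=mask),
        ("accuracy", "train"): gen_accuracy_maps(
            truth, concordance_low=concordance_low, concordance_high=concordance_high,
            seed=seeds[9], mask=mask),
        ("accuracy", "validation"): gen_accuracy_maps(
            truth, concordance_low=concordance_low, concordance_high=concordance_high,
            modality="audio+visual", seed=seeds[10], mask=mask),
    }
    return SyntheticStudy(truth=truth, trials=trials, ratings=ratings,
                          beta_maps=beta_maps, observer_accuracy=accuracy)
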