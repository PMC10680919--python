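"""Orchestration, file formats, configuration and provenance.

Formats: NIfTI-1 for maps and masks (one 3-D volume per subject x
condition x level, named ``sub-<id>_cond-<condition>_level-<level>_beta``),
CSV for rating streams, TSV for tables, JSON for reports and model
sidecars, YAML for run configuration. Geometry is never resampled: maps
must match the mask's shape and affine exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import nibabel as nib

from . import alignment as _alignment
from . import evaluate as _evaluate
from . import lasso_pcr as _lasso
from . import ratings as _ratings
from . import separability as _separability
from . import synthetic as _synthetic
from .glm import BetaMapSet
from .lasso_pcr import PatternModel

logger = logging.getLogger(__name__)

RATINGS_COLUMNS = ["subject_id", "role", "trial_id", "modality", "time_s", "rating"]
BETA_NAME_RE = re.compile(
    r"^sub-(?P<subject>[A-Za-z0-9]+)_cond-(?P<condition>ground_truth|inference|accuracy)"
    r"_level-(?P<level>[1-5]|low|high)_beta\.nii(\.gz)?$"
)


class FormatError(ValueError):
    """A file does not match the documented dialect."""


class GeometryError(ValueError):
    """NIfTI affine or shape mismatch; resampling is refused."""


@dataclass
class RunConfig:
    """Everything a run needs, round-trippable through YAML.

    Every stochastic stage has its own explicit seed (derived from
    ``seed`` when not given).
    """

    out_dir: str = "run"
    n_subjects: int = 20
    n_voxels: int = 500
    tr_s: float = 2.0
    lasso_num: int = 120
    n_boot: int = 200
    n_perm: int = 100
    svm_c: float = 1.0
    alignment_variant: str = "fisher"
    q: float = 0.05
    cluster_k: int = 25
    downsample_aggregator: str = "mean"
    validation_effect_scale: float = 0.6
    concordance_low: float = -0.3
    concordance_high: float = 0.35
    seed: int | None = 0
    stage_seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None and not self.stage_seeds:
            raise ValueError("config must fix a seed for every stochastic stage")
        for i, stage in enumerate(
                ("simulate", "train_gt", "train_inf", "bootstrap", "permutation")):
            self.stage_seeds.setdefault(
                stage, int(np.random.SeedSequence([self.seed or 0, i])
                           .generate_state(1)[0] % 2**31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Ratings CSV
# ---------------------------------------------------------------------------

def write_ratings_csv(series: list[_ratings.RatingSeries], path: str | Path) -> None:
    frames = [pd.DataFrame({
        "subject_id": s.subject_id, "role": s.role, "trial_id": s.trial_id,
        "modality": s.modality, "time_s": s.time_s, "rating": s.rating,
    }) for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> list[_ratings.RatingSeries]:
    """Read the ratings dialect; malformed rows are reported by line number."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty ratings file") from exc
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no rating rows")
    bad = df.index[(df.rating < 0) | (df.rating > 100) | df.rating.isna()]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:5]]  # header is line 1
        raise FormatError(f"{path}: rating outside [0, 100] at line(s) {rows}")
    out = []
    for (sid, role, trial, modality), grp in df.groupby(
            ["subject_id", "role", "trial_id", "modality"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(_ratings.RatingSeries(
            subject_id=str(sid), role=str(role), trial_id=str(trial),
            modality=str(modality), time_s=grp.time_s.to_numpy(),
            rating=grp.rating.to_numpy()))
    return out


# ---------------------------------------------------------------------------
# NIfTI beta maps
# ---------------------------------------------------------------------------

def beta_map_filename(subject: str, condition: str, level: object) -> str:
    return f"sub-{subject}_cond-{condition}_level-{level}_beta.nii.gz"


def write_beta_maps(maps: BetaMapSet, out_dir: str | Path) -> None:
    """One 3-D NIfTI per (subject, level), plus the shared mask volume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = maps.mask if maps.mask is not None else np.ones((1, 1, maps.n_voxels), bool)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), out / "mask.nii.gz")
    for (subject, level), vec in maps.maps.items():
        vol = np.zeros(mask.shape, dtype=np.float32)
        vol[mask] = vec.astype(np.float32)
        sid = subject.removeprefix("sub-")
        nib.save(nib.Nifti1Image(vol, affine),
                 out / beta_map_filename(sid, maps.condition, level))


def read_beta_maps(map_dir: str | Path, mask_path: str | Path | None = None,
                   condition: str | None = None) -> BetaMapSet:
    """Load a directory of beta NIfTIs into masked voxel vectors.

    Filenames must follow ``sub-<id>_cond-<condition>_level-<level>_beta``;
    all volumes must share the mask's shape and affine exactly.
    """
    map_dir = Path(map_dir)
    mask_path = Path(mask_path) if mask_path else map_dir / "mask.nii.gz"
    mask_img = nib.load(mask_path)
    mask = np.asarray(mask_img.dataobj).astype(bool)
    maps: dict[tuple[str, object], np.ndarray] = {}
    prov: dict[tuple[str, object], str] = {}
    conditions = set()
    for f in sorted(map_dir.glob("*_beta.nii*")):
        m = BETA_NAME_RE.match(f.name)
        if not m:
            raise FormatError(
                f"{f.name}: expected sub-<id>_cond-<condition>_level-<level>_beta.nii[.gz]")
        if condition is not None and m["condition"] != condition:
            continue
        img = nib.load(f)
        if img.shape != mask.shape or not np.allclose(img.affine, mask_img.affine):
            raise GeometryError(f"{f.name}: shape/affine differs from mask (no resampling)")
        level: object = int(m["level"]) if m["level"].isdigit() else m["level"]
        key = (f"sub-{m['subject']}", level)
        maps[key] = np.asarray(img.dataobj, dtype=np.float64)[mask]
        prov[key] = f.name
        conditions.add(m["condition"])
    if not maps:
        raise FormatError(f"{map_dir}: no beta maps found")
    if condition is None and len(conditions) > 1:
        raise FormatError(f"{map_dir}: multiple conditions {sorted(conditions)}; pass condition=")
    return BetaMapSet(condition=condition or conditions.pop(), maps=maps,
                      mask=mask, affine=mask_img.affine, provenance=prov)


# ---------------------------------------------------------------------------
# Models and reports
# ---------------------------------------------------------------------------

def write_model(model: PatternModel, out_dir: str | Path, name: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = model.mask if model.mask is not None else np.ones((1, 1, model.weights.size), bool)
    affine = model.affine if model.affine is not None else np.eye(4)
    vol = np.zeros(mask.shape, dtype=np.float32)
    vol[mask] = model.weights.astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine), out / f"{name}_weights.nii.gz")
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), out / f"{name}_mask.nii.gz")
    (out / f"{name}.json").write_text(json.dumps(
        {"intercept": model.intercept, "metadata": model.metadata}, indent=2))


def read_model(model_dir: str | Path, name: str) -> PatternModel:
    d = Path(model_dir)
    sidecar = json.loads((d / f"{name}.json").read_text())
    mask_img = nib.load(d / f"{name}_mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    weights = np.asarray(nib.load(d / f"{name}_weights.nii.gz").dataobj,
                         dtype=np.float64)[mask]
    return PatternModel(weights=weights, intercept=float(sidecar["intercept"]),
                        mask=mask, affine=mask_img.affine,
                        metadata=sidecar["metadata"])


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated study and write artifacts.

    Stages: simulate -> train both signatures (LOO-CV) -> validate on the
    unimodal condition -> per-level SVM separability -> alignment test.
    Every report is stamped with the config digest; a stage failure halts
    the run with the stage name and a manifest of what was produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stamp = {"config_digest": config.digest(), "stage_seeds": config.stage_seeds}
    manifest: list[str] = ["config.yaml"]
    results: dict = {"stamp": stamp}
    stage = "simulate"
    try:
        study = _synthetic.simulate_study(
            n_subjects=config.n_subjects, n_voxels=config.n_voxels,
            seed=config.stage_seeds["simulate"],
            validation_effect_scale=config.validation_effect_scale,
            concordance_low=config.concordance_low,
            concordance_high=config.concordance_high,
            n_observer_ratings=min(config.n_subjects, 5))
        write_ratings_csv(study.ratings, out / "ratings.csv")
        manifest.append("ratings.csv")

        models: dict[str, PatternModel] = {}
        for cond, stage_name in (("ground_truth", "train_gt"), ("inference", "train_inf")):
            stage = stage_name
            train_set = study.beta_maps[(cond, "train")]
            cv = _lasso.loo_cv(train_set, config.lasso_num,
                               seed=config.stage_seeds[stage_name])
            model = _lasso.fit_signature(train_set, config.lasso_num,
                                         seed=config.stage_seeds[stage_name])
            models[cond] = model
            write_model(model, out / "models", cond)
            results[f"cv_{cond}"] = {"mean_r": cv.mean_r, "se_r": cv.se_r,
                                     "per_subject_r": cv.per_subject_r}
            manifest += [f"models/{cond}_weights.nii.gz", f"models/{cond}.json"]

        stage = "validate"
        for cond, other in (("ground_truth", "inference"), ("inference", "ground_truth")):
            rep = _evaluate.validate_model(models[cond],
                                           study.beta_maps[(cond, "validation")],
                                           study.beta_maps[(other, "validation")])
            results[f"validation_{cond}"] = {
                "mean_r_own": rep.mean_r_own, "mean_r_other": rep.mean_r_other,
                "t_own": rep.t_own, "p_own": rep.p_own,
                "t_paired": rep.t_paired, "p_paired": rep.p_paired,
                "ci_paired": rep.ci_paired, "cohens_d": rep.cohens_d}
        results["pattern_cosine"] = _evaluate.cosine_similarity(
            models["ground_truth"].weights, models["inference"].weights)

        stage = "separate"
        sep = {}
        for level in range(1, 6):
            res = _separability.train_svm_per_level(
                study.beta_maps[("ground_truth", "train")],
                study.beta_maps[("inference", "train")], level, C=config.svm_c)
            sep[level] = {"accuracy": res.accuracy, "se": res.accuracy_se,
                          "auc": res.auc, "p": res.p_binomial}
        results["separability"] = sep

        stage = "align"
        expr = _alignment.accuracy_expressions(
            models["ground_truth"], models["inference"],
            study.beta_maps[("accuracy", "train")])
        ares = _alignment.alignment_test(expr, config.alignment_variant)
        results["alignment"] = {"r_low": ares.r_low, "r_high": ares.r_high,
                                "z": ares.z, "p": ares.p, "variant": ares.variant}
        expr.to_csv(out / "expressions.tsv", sep="\t", index=False)
        manifest.append("expressions.tsv")
        expr_val = _alignment.accuracy_expressions(
            models["ground_truth"], models["inference"],
            study.beta_maps[("accuracy", "validation")])
        ares_val = _alignment.alignment_test(expr_val, config.alignment_variant)
        results["alignment_validation"] = {
            "r_low": ares_val.r_low, "r_high": ares_val.r_high,
            "z": ares_val.z, "p": ares_val.p, "variant": ares_val.variant}
    except Exception as exc:
        write_json({"failed_stage": stage, "manifest": manifest, "error": str(exc)},
                   out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    write_json({"failed_stage": None, "manifest": manifest}, out / "manifest.json")
    write_json(results, out / "results.json")
    logger.info("pipeline complete: %s", out / "results.json")
    return results
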