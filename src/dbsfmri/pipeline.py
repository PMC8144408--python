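"""End-to-end driver: runs -> t-maps -> features -> models -> report.

Two entry paths produce the same feature table:

* :func:`cohort_features` streams the synthetic generator straight through
  the first-level GLM (no intermediate files) — the path used by tests and
  the acceptance script;
* :func:`manifest_features` reads runs and motion traces from disk given a
  cohort manifest — the path used by the command-line interface.

Model training fits three LDA variants on the training cohort (combined,
contact-only, voltage-only) and evaluates each on both held-out cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .atlas import RoiAtlas, make_default_atlas
from .classifier import cross_validate, evaluate, fit_lda
from .config import PipelineConfig, config_hash
from .features import compute_features, feature_names
from .glm import BoldRun, first_level
from .synthetic import iter_cohort

__all__ = [
    "cohort_features",
    "manifest_features",
    "train_models",
    "run_pipeline",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = [
    "patient_id",
    "run_id",
    "mode",
    "status",
    "contact_distance_mm",
    "voltage_offset_v",
    "target",
    "cohort",
    "divisor",
    "degenerate",
    "n_censored",
]


def _feature_row(row: dict, run, trace, atlas: RoiAtlas, config: PipelineConfig) -> dict:
    tmap, diag = first_level(
        run,
        trace,
        fwhm_vox=config.glm.fwhm_vox,
        threshold_mm=config.glm.threshold_mm,
        hrf_params=config.hrf,
    )
    fv = compute_features(tmap, atlas, row["mode"], config.features.epsilon)
    out = dict(row)
    out["divisor"] = fv.divisor
    out["degenerate"] = fv.degenerate
    out["n_censored"] = diag["n_censored"]
    out.update(dict(zip(fv.names, fv.values)))
    return out


def cohort_features(
    config: PipelineConfig, seed: int, atlas: RoiAtlas | None = None
) -> pd.DataFrame:
    """Simulate the configured cohort and extract features for every run."""
    atlas = atlas or make_default_atlas(config.cohort.grid_shape)
    rows = [
        _feature_row(row, run, trace, atlas, config)
        for row, run, trace in iter_cohort(config.cohort, seed, atlas)
    ]
    return pd.DataFrame(rows)


def manifest_features(
    manifest: pd.DataFrame,
    base_dir,
    config: PipelineConfig,
    atlas: RoiAtlas | None = None,
) -> pd.DataFrame:
    """Feature table for runs stored on disk (per-manifest paths)."""
    atlas = atlas or make_default_atlas(config.cohort.grid_shape)
    base = Path(base_dir)
    rows = []
    for rec in manifest.to_dict("records"):
        try:
            data, _ = _io.read_nifti(base / rec["run_path"])
            trace = _io.read_motion(base / rec["motion_path"])
            run = BoldRun(
                data=np.asarray(data, dtype=float),
                tr_s=config.paradigm.tr_s,
                paradigm=config.paradigm,
                ids={"patient_id": rec["patient_id"]},
            )
            row = {k: rec[k] for k in rec if k not in ("run_path", "motion_path")}
            row.setdefault("run_id", Path(rec["run_path"]).name.split(".")[0])
            rows.append(_feature_row(row, run, trace, atlas, config))
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed on run {rec.get('run_path')}: {exc}"
            ) from exc
    return pd.DataFrame(rows)


def _xy(features: pd.DataFrame, atlas: RoiAtlas):
    cols = list(feature_names(atlas))
    X = features[cols].to_numpy(dtype=float)
    y = (features["status"] == "optimal").to_numpy().astype(int)
    groups = features["patient_id"].to_numpy()
    return X, y, groups


def train_models(features: pd.DataFrame, atlas: RoiAtlas, config: PipelineConfig) -> dict:
    """Fit combined / contact-only / voltage-only models on the train cohort."""
    train = features[features["cohort"] == "train"]
    models = {}
    for name, subset in (
        ("combined", train),
        ("contact", train[train["mode"] == "contact"]),
        ("voltage", train[train["mode"] == "voltage"]),
    ):
        X, y, groups = _xy(subset, atlas)
        models[name] = fit_lda(
            X,
            y,
            shrinkage=config.classifier.shrinkage,
            feature_names=feature_names(atlas),
            train_patients=set(groups),
        )
    return models


def run_pipeline(
    features: pd.DataFrame,
    atlas: RoiAtlas,
    config: PipelineConfig,
    out_dir=None,
) -> dict:
    """Train, cross-validate, and evaluate; optionally write the report.

    Returns a JSON-serializable report: per-model CV accuracy on the train
    cohort and a confusion matrix for each held-out test cohort (skipped
    with a note when a cohort is empty).
    """
    cfg_hash = config_hash(config)
    models = train_models(features, atlas, config)
    report: dict = {"config_hash": cfg_hash, "models": {}}
    train = features[features["cohort"] == "train"]
    report["n_train_patients"] = int(train["patient_id"].nunique())
    report["n_censored_total"] = int(features["n_censored"].sum())
    report["n_degenerate_divisors"] = int(features["degenerate"].sum())

    for name, model in models.items():
        subset = train if name == "combined" else train[train["mode"] == name]
        X, y, groups = _xy(subset, atlas)
        cv = cross_validate(
            X,
            y,
            groups,
            k=config.classifier.k_folds,
            shrinkage=config.classifier.shrinkage,
            seed=config.classifier.seed,
        )
        entry = {
            "cv_accuracy": cv.pooled_accuracy,
            "fold_accuracies": cv.fold_accuracies,
            "tests": {},
        }
        for cohort in ("test_programmed", "test_naive"):
            sub = features[features["cohort"] == cohort]
            if sub.empty:
                entry["tests"][cohort] = {"skipped": "cohort empty"}
                continue
            Xt, yt, gt = _xy(sub, atlas)
            cm = evaluate(model, Xt, yt, test_patients=gt)
            entry["tests"][cohort] = cm.as_dict()
        report["models"][name] = entry

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        for name, model in models.items():
            _io.save_model(out / f"model_{name}.json", model, cfg_hash)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
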