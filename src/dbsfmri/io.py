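"""File formats: NIfTI volumes, CSV manifests and features, JSON models.

Conventions: NIfTI-1 (optionally gzipped) with a 4 mm isotropic affine by
default; t-maps carry their degrees of freedom in a JSON sidecar; CSVs are
comma-separated UTF-8 with a mandatory header row; LDA models serialize to
JSON including the feature order and the config hash they were trained
under.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .classifier import LdaModel
from .config import PipelineConfig, config_from_dict
from .glm import MotionTrace, TMap

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_tmap",
    "read_tmap",
    "read_motion",
    "read_manifest",
    "load_config",
    "save_model",
    "load_model",
]

DEFAULT_AFFINE = np.diag([4.0, 4.0, 4.0, 1.0])

MANIFEST_COLUMNS = [
    "patient_id",
    "run_path",
    "motion_path",
    "mode",
    "status",
    "contact_distance_mm",
    "voltage_offset_v",
    "target",
    "cohort",
]


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), affine if affine is not None else DEFAULT_AFFINE)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # malformed header or payload
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    return data, img.affine


def write_tmap(path, tmap: TMap, affine: np.ndarray | None = None) -> None:
    """t-map as NIfTI plus a JSON sidecar carrying df/contrast/flag count."""
    path = Path(path)
    write_nifti(path, tmap.t.astype(np.float32), affine)
    sidecar = {
        "df": int(tmap.df),
        "contrast": tmap.contrast,
        "n_flagged": int(tmap.flags.sum()),
    }
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    side_path = path.parent / (stem + ".json")
    side_path.write_text(json.dumps(sidecar, indent=1))


def read_tmap(path) -> TMap:
    path = Path(path)
    data, _ = read_nifti(path)
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    side_path = path.parent / (stem + ".json")
    sidecar = json.loads(side_path.read_text())
    return TMap(
        t=np.asarray(data, dtype=float),
        df=int(sidecar["df"]),
        flags=np.zeros(data.shape, dtype=bool),
        contrast=sidecar.get("contrast", "on_gt_off"),
    )


def read_motion(path) -> MotionTrace:
    df = pd.read_csv(path)
    return MotionTrace(df[["tx", "ty", "tz", "rx", "ry", "rz"]].to_numpy())


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad_status = set(df["status"]) - {"optimal", "non_optimal"}
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    if check_paths:
        for rel in df["run_path"]:
            if not (path.parent / rel).exists():
                raise FileNotFoundError(f"run file missing: {path.parent / rel}")
    return df


def load_config(path=None) -> PipelineConfig:
    """YAML config -> validated PipelineConfig (defaults when path is None)."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text())
    return config_from_dict(data)


def save_model(path, model: LdaModel, cfg_hash: str = "") -> None:
    payload = {
        "feature_names": list(model.feature_names or []),
        "mu0": model.mu0.tolist(),
        "mu1": model.mu1.tolist(),
        "cov": model.cov.tolist(),
        "shrinkage": model.shrinkage,
        "priors": list(model.priors),
        "w": model.w.tolist(),
        "b": model.b,
        "train_patients": sorted(model.train_patients),
        "config_hash": cfg_hash,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path, expected_hash: str | None = None) -> tuple[LdaModel, str]:
    payload = json.loads(Path(path).read_text())
    stored = payload.get("config_hash", "")
    if expected_hash is not None and stored and stored != expected_hash:
        raise ValueError(
            f"model config hash {stored} does not match current config {expected_hash}"
        )
    model = LdaModel(
        mu0=np.array(payload["mu0"]),
        mu1=np.array(payload["mu1"]),
        cov=np.array(payload["cov"]),
        shrinkage=float(payload["shrinkage"]),
        priors=tuple(payload["priors"]),
        w=np.array(payload["w"]),
        b=float(payload["b"]),
        feature_names=tuple(payload["feature_names"]) or None,
        train_patients=frozenset(payload["train_patients"]),
    )
    return model, stored
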