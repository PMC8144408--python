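"""Pipeline configuration: schema, defaults, and hashing.

All tunables of the end-to-end analysis live here so one file pins the
study conditions: paradigm timing, HRF parameters, generator noise and
effect sizes, GLM thresholds, the feature-normalization floor, and the
classifier settings.  Unknown keys in a user config are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .hrf import HrfParams, Paradigm
from .synthetic import CohortSpec, NoiseModel

__all__ = ["GlmConfig", "FeatureConfig", "ClassifierConfig", "PipelineConfig",
           "config_from_dict", "config_hash"]


@dataclass(frozen=True)
class GlmConfig:
    threshold_mm: float = 1.5
    p_voxel: float = 0.001
    k_min: int = 50
    connectivity: int = 26
    fwhm_vox: float = 1.5  # ~6 mm FWHM at 4 mm isotropic voxels


@dataclass(frozen=True)
class FeatureConfig:
    epsilon: float = 1e-6


@dataclass(frozen=True)
class ClassifierConfig:
    shrinkage: float = 0.1
    k_folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    paradigm: Paradigm = field(default_factory=Paradigm)
    hrf: HrfParams = field(default_factory=HrfParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    glm: GlmConfig = field(default_factory=GlmConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    defaults = cls()
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        default = getattr(defaults, f.name)
        if isinstance(val, dict) and dataclasses.is_dataclass(default):
            val = _build(type(default), val)
        elif isinstance(default, tuple) and isinstance(val, (list, tuple)):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig from nested plain dicts (e.g. YAML)."""
    return _build(PipelineConfig, data or {})


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    return obj


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of a config."""
    payload = json.dumps(_as_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
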