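"""ROI t-value feature extraction and side-effect normalization.

From an unthresholded first-level t-map, each of the 16 atlas regions
contributes two nonnegative statistics: the mean of its strictly positive
voxel t-values (BOLD increases) and the mean magnitude of its strictly
negative voxel t-values (BOLD decreases) — 32 features per tested setting.

Features are then rescaled by a single mode-dependent divisor: the pooled
mean of strictly positive voxel t-values over the side-effect regions
(visual cortex + operculum) in contact mode, or over the contralateral
primary motor cortex in voltage mode.  The divisor cancels any global t-map
scale, making features comparable across patients while penalizing
side-effect recruitment.  A divisor at or below ``epsilon`` is floored and
flagged rather than treated as fatal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import RoiAtlas
from .glm import TMap

__all__ = [
    "RawRoiStats",
    "FeatureVector",
    "extract_roi_stats",
    "normalize_features",
    "feature_names",
    "compute_features",
]

DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class RawRoiStats:
    """Per-region sign-split mean t statistics (all nonnegative)."""

    pos_mean: np.ndarray  # mean of strictly positive voxel t (0 if none)
    neg_mean: np.ndarray  # mean |t| of strictly negative voxels (0 if none)
    voxel_counts: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.pos_mean) == len(self.neg_mean) == len(self.voxel_counts)):
            raise ValueError("per-region arrays must have equal length")
        if (self.pos_mean < 0).any() or (self.neg_mean < 0).any():
            raise ValueError("sign-split means must be nonnegative")


@dataclass(frozen=True)
class FeatureVector:
    """32 ordered normalized features: positive block then negative block."""

    values: np.ndarray
    names: tuple[str, ...]
    mode: str
    divisor: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")
        if not np.isfinite(self.values).all():
            raise ValueError("features must be finite")


def feature_names(atlas: RoiAtlas) -> tuple[str, ...]:
    """Deterministic feature order: <region>_pos in atlas label order, then _neg."""
    return tuple(f"{n}_pos" for n in atlas.names) + tuple(
        f"{n}_neg" for n in atlas.names
    )


def extract_roi_stats(tmap: TMap, atlas: RoiAtlas) -> RawRoiStats:
    """Sign-split per-region means of the unthresholded t-map.

    Zeros belong to neither sign partition; a region with no voxels of a
    given sign contributes 0 for that feature.
    """
    if tmap.t.shape != atlas.labels.shape:
        raise ValueError("t-map and atlas grids do not match")
    pos = np.zeros(atlas.n_regions)
    neg = np.zeros(atlas.n_regions)
    counts = np.zeros(atlas.n_regions, dtype=int)
    for i, name in enumerate(atlas.names):
        vals = tmap.t[atlas.mask(name)]
        counts[i] = vals.size
        p = vals[vals > 0]
        n = vals[vals < 0]
        pos[i] = p.mean() if p.size else 0.0
        neg[i] = (-n).mean() if n.size else 0.0
    return RawRoiStats(pos_mean=pos, neg_mean=neg, voxel_counts=counts)


def _divisor(tmap: TMap, atlas: RoiAtlas, mode: str) -> float:
    role = {"contact": "contact_normalizer", "voltage": "voltage_normalizer"}.get(mode)
    if role is None:
        raise ValueError(f"unknown mode {mode!r}")
    regions = atlas.names_with_role(role)
    if not regions:
        raise ValueError(f"atlas has no {role} regions")
    pooled = np.concatenate([tmap.t[atlas.mask(n)] for n in regions])
    pooled = pooled[pooled > 0]
    return float(pooled.mean()) if pooled.size else 0.0


def normalize_features(
    raw: RawRoiStats,
    mode: str,
    atlas: RoiAtlas,
    tmap: TMap,
    epsilon: float = DEFAULT_EPSILON,
) -> FeatureVector:
    """Divide all 32 raw statistics by the mode-dependent pooled divisor.

    The divisor is the mean of strictly positive voxel t-values pooled over
    the flagged normalizer regions of the t-map itself (not the per-region
    summary), recorded in the output.  Divisors <= epsilon are floored to
    epsilon and flagged degenerate.
    """
    div = _divisor(tmap, atlas, mode)
    degenerate = div <= epsilon
    used = max(div, epsilon)
    values = np.concatenate([raw.pos_mean, raw.neg_mean]) / used
    return FeatureVector(
        values=values,
        names=feature_names(atlas),
        mode=mode,
        divisor=used,
        degenerate=degenerate,
    )


def compute_features(
    tmap: TMap, atlas: RoiAtlas, mode: str, epsilon: float = DEFAULT_EPSILON
) -> FeatureVector:
    """Extract and normalize in one call."""
    return normalize_features(extract_roi_stats(tmap, atlas), mode, atlas, tmap, epsilon)
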