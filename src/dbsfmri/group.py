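"""Cohort-level analyses: contact distances, rank-sum tests, group t-maps.

Contact positions on the lead are abstract indices; distances are converted
to millimetres using the lead geometry (4 contacts of 1.5 mm width with
1.5 mm gaps by default, i.e. a 3 mm center-to-center pitch).  Feature
profiles across the distance bins 0/3/6/9 mm are compared with Wilcoxon
rank-sum (Mann-Whitney) tests — exact enumeration for small samples, normal
approximation with tie and continuity corrections otherwise.  The
second-level model is the one-sample special case: a voxelwise t test of
per-subject normalized contrast maps against zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .glm import T_SENTINEL, TMap

__all__ = [
    "LeadGeometry",
    "DistanceProfile",
    "map_contact_distance",
    "rank_sum_test",
    "distance_profile",
    "second_level_ttest",
    "peak_locations",
]

EXACT_ENUMERATION_MAX_N = 10


@dataclass(frozen=True)
class LeadGeometry:
    """Contact count and spacing of a DBS lead (default: 4 x 1.5 mm / 1.5 mm)."""

    n_contacts: int = 4
    contact_width_mm: float = 1.5
    contact_gap_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.n_contacts < 2:
            raise ValueError("a lead needs at least 2 contacts")
        if self.contact_width_mm <= 0 or self.contact_gap_mm <= 0:
            raise ValueError("contact width and gap must be > 0")

    @property
    def pitch_mm(self) -> float:
        return self.contact_width_mm + self.contact_gap_mm


@dataclass(frozen=True)
class DistanceProfile:
    """Per-distance-bin summary of one normalized feature."""

    bins_mm: tuple[float, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    sem: tuple[float, ...]
    p_vs_optimal: dict[float, float]
    feature: str


def map_contact_distance(
    geometry: LeadGeometry, optimal_index: int
) -> np.ndarray:
    """Center-to-center distance of every contact from the optimal one (mm)."""
    if not (0 <= optimal_index < geometry.n_contacts):
        raise ValueError("optimal_index out of range")
    idx = np.arange(geometry.n_contacts)
    return np.abs(idx - optimal_index) * geometry.pitch_mm


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a with midrank tie handling."""
    pooled = np.concatenate([a, b])
    ranks = _stats.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return ra - a.size * (a.size + 1) / 2.0


def rank_sum_test(
    a, b, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    For pooled sample sizes of at most 10 the null distribution of U is
    enumerated exactly over all assignments of pooled midranks, so ties are
    handled exactly; larger samples use the normal approximation with tie
    and continuity corrections.  Returns (U for sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    u = _u_statistic(a, b)

    if a.size + b.size <= EXACT_ENUMERATION_MAX_N:
        pooled = np.concatenate([a, b])
        ranks = _stats.rankdata(pooled)
        na = a.size
        offset = na * (na + 1) / 2.0
        us = np.array(
            [sum(c) - offset for c in combinations(ranks, na)]
        )
        tol = 1e-9
        p_le = np.mean(us <= u + tol)
        p_ge = np.mean(us >= u - tol)
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u), float(p)

    scipy_alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
    res = _stats.mannwhitneyu(
        a, b, alternative=scipy_alt[alternative], method="asymptotic"
    )
    return float(u), float(res.pvalue)


def distance_profile(
    features: pd.DataFrame,
    feature: str,
    distance_col: str = "contact_distance_mm",
) -> DistanceProfile:
    """Mean +/- SEM of one feature per contact-distance bin, with rank-sum
    p-values of each non-zero bin against the optimal (0 mm) bin."""
    if feature not in features.columns:
        raise ValueError(f"feature {feature!r} absent from table")
    table = features[features["mode"] == "contact"] if "mode" in features else features
    bins = sorted(table[distance_col].unique())
    if len(bins) < 2:
        raise ValueError("need at least 2 populated distance bins")
    groups = {d: table.loc[table[distance_col] == d, feature].to_numpy() for d in bins}
    n = tuple(len(groups[d]) for d in bins)
    mean = tuple(float(groups[d].mean()) for d in bins)
    sem = tuple(
        float(groups[d].std(ddof=1) / np.sqrt(len(groups[d])))
        if len(groups[d]) > 1
        else float("nan")
        for d in bins
    )
    p_vs = {}
    if 0.0 in groups:
        for d in bins:
            if d != 0.0:
                _, p = rank_sum_test(groups[0.0], groups[d])
                p_vs[float(d)] = p
    return DistanceProfile(
        bins_mm=tuple(float(d) for d in bins),
        n=n,
        mean=mean,
        sem=sem,
        p_vs_optimal=p_vs,
        feature=feature,
    )


def second_level_ttest(maps: list[np.ndarray]) -> TMap:
    """Voxelwise one-sample t of per-subject maps against 0 (df = n - 1).

    Voxels with zero variance get the signed sentinel when their mean is
    nonzero (flagged), and t = 0 when the mean is zero as well.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 maps")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("maps must share a common grid")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero_var, np.sign(mean) * T_SENTINEL, t)
    t = np.nan_to_num(t, nan=0.0)
    return TMap(t=t, df=n - 1, flags=zero_var)


def peak_locations(tmap: TMap, sign: str = "positive") -> tuple[tuple[int, ...], float]:
    """Coordinate and value of the extreme voxel (first in scan order on ties)."""
    t = tmap.t
    if np.isnan(t).all():
        raise ValueError("map is all-NaN")
    if sign == "positive":
        flat = np.nanargmax(t)
    elif sign == "negative":
        flat = np.nanargmin(t)
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    coord = np.unravel_index(flat, t.shape)
    return tuple(int(c) for c in coord), float(t[coord])
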