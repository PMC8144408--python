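"""Synthetic 16-region label atlas with hemisphere and functional-role flags.

Sixteen regions of interest (ROIs): eight anatomical roles mirrored across
the two hemispheres — primary motor cortex (M1), supplementary motor area
(SMA), thalamus, pallidum, anterior cerebellum, posterior cerebellum, visual
cortex, and operculum.  Roles drive the downstream analysis:

* ``motor`` regions carry the stimulation response of interest;
* ``contact_normalizer`` regions (visual cortex and operculum, both sides)
  are side-effect areas recruited by non-optimal contacts and provide the
  feature-normalization divisor in contact mode;
* ``voltage_normalizer`` (right, i.e. contralateral, M1) provides the
  divisor in voltage mode.

The atlas is an abstract stand-in placed on a small isotropic grid: spheres
at fixed fractional coordinates, right-hemisphere regions obtained by
mirroring the left masks across the first-axis midplane so left/right voxel
counts match exactly.  "Left" is the lower first-axis index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiAtlas", "make_default_atlas", "ROLE_ORDER"]

# anatomical role order; label i*2+1 = left, i*2+2 = right
ROLE_ORDER = (
    "m1",
    "sma",
    "thalamus",
    "pallidum",
    "ant_cerebellum",
    "post_cerebellum",
    "visual",
    "operculum",
)

# sphere centers for the left hemisphere, fractional coordinates of a cubic
# grid (first axis < 0.5); chosen so all 16 spheres are pairwise disjoint
_LEFT_CENTERS_FRAC = {
    "m1": (7 / 24, 7 / 24, 19 / 24),
    "sma": (7 / 24, 14 / 24, 19 / 24),
    "thalamus": (9 / 24, 12 / 24, 12 / 24),
    "pallidum": (7 / 24, 18 / 24, 11 / 24),
    "ant_cerebellum": (7 / 24, 7 / 24, 5 / 24),
    "post_cerebellum": (7 / 24, 15 / 24, 4 / 24),
    "visual": (7 / 24, 21 / 24, 5 / 24),
    "operculum": (4 / 24, 12 / 24, 13 / 24),
}

_RADIUS_FRAC = 2.5 / 24  # sphere radius as a fraction of the smallest dim

MOTOR_ROLES = {"m1", "sma", "thalamus", "ant_cerebellum"}


@dataclass(frozen=True)
class RoiAtlas:
    """Integer label grid (0 = background, 1..16 = regions) plus metadata."""

    labels: np.ndarray
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    roles: dict[str, frozenset[str]] = field(compare=False)

    def __post_init__(self) -> None:
        found = set(np.unique(self.labels)) - {0}
        if found != set(range(1, len(self.names) + 1)):
            raise ValueError("labels must be exactly 1..n_regions plus background 0")
        for lab in range(1, len(self.names) + 1):
            if not (self.labels == lab).any():
                raise ValueError(f"region {self.names[lab - 1]} is empty")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def label_of(self, name: str) -> int:
        return self.names.index(name) + 1

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    def names_with_role(self, role: str) -> list[str]:
        return [n for n in self.names if role in self.roles[n]]

    def mirror_name(self, name: str) -> str:
        hemi, _, role = name.partition("_")
        other = "right" if hemi == "left" else "left"
        return f"{other}_{role}"


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 < radius**2


def make_default_atlas(grid_shape=(24, 24, 24)) -> RoiAtlas:
    """Place the 16 default regions on a grid (each dimension >= 16).

    Right-hemisphere masks are mirror images of the left ones, so paired
    regions always have equal voxel counts.
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError("grid must be 3-D with every dimension >= 16")
    radius = _RADIUS_FRAC * min(shape)
    labels = np.zeros(shape, dtype=np.int16)
    names: list[str] = []
    hemis: list[str] = []
    lab = 0
    for role in ROLE_ORDER:
        cf = _LEFT_CENTERS_FRAC[role]
        center = tuple(c * s for c, s in zip(cf, shape))
        left = _sphere_mask(shape, center, radius)
        right = left[::-1, :, :]
        for hemi, mask in (("left", left), ("right", right)):
            lab += 1
            if not mask.any():
                raise ValueError(f"grid too small: region {hemi}_{role} is empty")
            if (labels[mask] != 0).any():
                raise ValueError(f"grid too small: region {hemi}_{role} overlaps")
            labels[mask] = lab
            names.append(f"{hemi}_{role}")
            hemis.append(hemi)

    roles: dict[str, frozenset[str]] = {}
    for name in names:
        hemi, _, role = name.partition("_")
        flags: set[str] = set()
        if role in MOTOR_ROLES:
            flags.add("motor")
        if role in ("visual", "operculum"):
            flags.add("contact_normalizer")
        if name == "right_m1":
            flags.add("voltage_normalizer")
        roles[name] = frozenset(flags)

    return RoiAtlas(
        labels=labels, names=tuple(names), hemispheres=tuple(hemis), roles=roles
    )
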