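"""DBS ON/OFF block paradigm and canonical haemodynamic response model.

A stimulation session alternates the implanted electrode between ON and OFF
in fixed-length blocks (30 s each by default) after an initial OFF lead-in,
while BOLD volumes are acquired at a constant repetition time (TR).  The
expected BOLD time course is the block boxcar convolved with the canonical
double-gamma haemodynamic response function (HRF)

    h(t) = g(t; a1, b1) - c * g(t; a2, b2),

where ``g`` is the gamma probability density, the first term is the positive
response peaking near 5 s and the second the late undershoot near 15 s.  The
kernel is rescaled to unit peak so that regressor amplitudes are expressed
relative to the response maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "Paradigm",
    "HrfParams",
    "canonical_hrf",
    "build_boxcar",
    "build_task_regressor",
    "task_regressor",
]


@dataclass(frozen=True)
class Paradigm:
    """Timing of one ON/OFF cycling session.

    Parameters
    ----------
    lead_in_s:
        Seconds of initial stimulation-OFF baseline before the first ON block.
    block_s:
        Seconds per ON block and per OFF block (equal by design).
    n_cycles:
        Number of ON/OFF cycles.
    tr_s:
        Volume repetition time in seconds.

    The default 30 s lead-in followed by six 30 s ON / 30 s OFF cycles gives
    a 390 s (6.5 min) session of 195 volumes at TR = 2 s.
    """

    lead_in_s: float = 30.0
    block_s: float = 30.0
    n_cycles: int = 6
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.lead_in_s < 0:
            raise ValueError("lead_in_s must be >= 0")
        if self.block_s <= 0:
            raise ValueError("block_s must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + 2.0 * self.block_s * self.n_cycles

    @property
    def n_volumes(self) -> int:
        return int(np.floor(self.duration_s / self.tr_s + 1e-9))

    def on_blocks(self) -> list[tuple[float, float]]:
        """[start, end) intervals, in seconds, of every ON block."""
        out = []
        for k in range(self.n_cycles):
            start = self.lead_in_s + 2.0 * self.block_s * k
            out.append((start, start + self.block_s))
        return out


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma kernel parameters (shapes unitless, rates in 1/s)."""

    a1: float = 6.0
    b1: float = 1.0
    a2: float = 16.0
    b2: float = 1.0
    c: float = 1.0 / 6.0
    dt_s: float = 0.1
    length_s: float = 32.0

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.c < 1):
            raise ValueError("undershoot ratio c must be in [0, 1)")
        if self.dt_s <= 0 or self.length_s <= 0:
            raise ValueError("dt_s and length_s must be > 0")


def canonical_hrf(params: HrfParams | None = None) -> np.ndarray:
    """Sample the peak-normalized double-gamma kernel on [0, length_s].

    Returns h(t) at steps of ``dt_s``; the maximum is exactly 1.
    """
    p = params or HrfParams()
    t = np.arange(0.0, p.length_s + 0.5 * p.dt_s, p.dt_s)
    h = _gamma_dist.pdf(t, p.a1, scale=1.0 / p.b1) - p.c * _gamma_dist.pdf(
        t, p.a2, scale=1.0 / p.b2
    )
    peak = h.max()
    if peak <= 0:
        raise ValueError("kernel has no positive peak; check parameters")
    return h / peak


def build_boxcar(paradigm: Paradigm) -> np.ndarray:
    """Per-volume ON/OFF indicator.

    Volume v is 1 iff its acquisition midpoint (v + 0.5) * TR falls inside an
    ON block.  For TR-commensurate block lengths this is unambiguous.
    """
    mid = (np.arange(paradigm.n_volumes) + 0.5) * paradigm.tr_s
    box = np.zeros(paradigm.n_volumes, dtype=float)
    for start, end in paradigm.on_blocks():
        box[(mid >= start) & (mid < end)] = 1.0
    return box


def build_task_regressor(
    boxcar: np.ndarray, hrf: np.ndarray, tr_s: float, dt_s: float = 0.1
) -> np.ndarray:
    """Convolve a per-volume boxcar with an HRF kernel sampled at dt_s.

    The boxcar is upsampled to the kernel grid (zero-stuffing, one unit
    impulse per acquired volume), convolved, and sampled back at volume
    times, truncated to the boxcar length.  A single ON volume therefore
    reproduces the kernel resampled at TR exactly, and the operation is
    linear in the boxcar.
    """
    boxcar = np.asarray(boxcar, dtype=float)
    if boxcar.size == 0:
        raise ValueError("boxcar must be nonempty")
    hrf = np.asarray(hrf, dtype=float)
    if hrf.size == 0:
        raise ValueError("HRF kernel must be nonempty")
    if tr_s <= 0:
        raise ValueError("tr_s must be > 0")
    up = tr_s / dt_s
    u = int(round(up))
    if abs(up - u) > 1e-9 or u < 1:
        raise ValueError("tr_s must be an integer multiple of dt_s")
    dense = np.zeros(boxcar.size * u)
    dense[::u] = boxcar
    conv = np.convolve(dense, hrf)
    return conv[::u][: boxcar.size]


def task_regressor(
    paradigm: Paradigm,
    hrf_params: HrfParams | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Convenience: boxcar -> convolved task regressor for a paradigm.

    With ``normalize`` the regressor is scaled to unit maximum magnitude so
    that a simulated amplitude of a% yields an a% signal excursion at the
    response peak; the shape is unchanged.
    """
    p = hrf_params or HrfParams()
    reg = build_task_regressor(
        build_boxcar(paradigm), canonical_hrf(p), paradigm.tr_s, p.dt_s
    )
    if normalize:
        m = np.abs(reg).max()
        if m > 0:
            reg = reg / m
    return reg
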