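"""Synthetic DBS-fMRI cohort generator.

Virtual patients receive unilateral left stimulation cycled ON/OFF while
4-D BOLD runs are "acquired" on a small isotropic grid.  Each tested setting
(an electrode contact or a voltage) maps to a deterministic spatial effect
template expressing the qualitative physiology:

* optimal STN stimulation: BOLD decrease in the left (ipsilateral) primary
  motor cortex, increase in the left thalamus and right (contralateral)
  anterior cerebellum;
* non-optimal contacts: the motor response shrinks linearly with the
  contact's distance from the optimal one while side-effect regions
  (visual cortex, operculum) are increasingly recruited;
* subtherapeutic voltage: same topography at reduced magnitude;
* supratherapeutic voltage: stronger motor response plus extra side-effect
  and contralateral (right-hemisphere) engagement;
* optimal GPi stimulation uses a distinct template variant emphasising the
  pallidum and thalamus.

Voxel time series are baseline * (1 + amplitude * regressor / 100 + drift +
AR(1) noise), with a slow random-walk motion trace carrying occasional
spikes larger than the 1.5 mm censoring threshold; spiked volumes also get a
global intensity glitch so censoring is consequential.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import RoiAtlas, make_default_atlas
from .glm import BoldRun, MotionTrace
from .hrf import HrfParams, Paradigm, task_regressor

__all__ = [
    "SettingLabel",
    "EffectTemplate",
    "NoiseModel",
    "CohortSpec",
    "effect_template",
    "simulate_run",
    "cohort_plan",
    "iter_cohort",
    "make_cohort",
]

SUBTHERAPEUTIC_OFFSET_V = -1.5  # volts below the optimal amplitude
SUPRATHERAPEUTIC_OFFSET_V = 1.0  # just below the side-effect threshold
MAX_DISTANCE_MM = 9.0  # furthest contact on the modeled 4-contact lead


@dataclass(frozen=True)
class SettingLabel:
    """One tested stimulation setting (a contact or a voltage)."""

    mode: str  # "contact" | "voltage"
    status: str  # "optimal" | "non_optimal"
    contact_distance_mm: float = 0.0
    voltage_class: str | None = None  # optimal|subtherapeutic|supratherapeutic
    voltage_offset_v: float = 0.0
    target: str = "STN"  # "STN" | "GPi"

    def __post_init__(self) -> None:
        if self.mode not in ("contact", "voltage"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.status not in ("optimal", "non_optimal"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.target not in ("STN", "GPi"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.mode == "contact":
            optimal = self.contact_distance_mm == 0
            if (self.status == "optimal") != optimal:
                raise ValueError("contact status inconsistent with distance")
        else:
            if self.voltage_class not in (
                "optimal",
                "subtherapeutic",
                "supratherapeutic",
            ):
                raise ValueError(f"unknown voltage class {self.voltage_class!r}")
            if (self.status == "optimal") != (self.voltage_class == "optimal"):
                raise ValueError("voltage status inconsistent with class")
            if (
                self.voltage_class == "subtherapeutic"
                and self.voltage_offset_v != SUBTHERAPEUTIC_OFFSET_V
            ):
                raise ValueError("subtherapeutic offset must be -1.5 V")

    @staticmethod
    def optimal_contact(target: str = "STN") -> "SettingLabel":
        return SettingLabel("contact", "optimal", 0.0, target=target)

    @staticmethod
    def contact(distance_mm: float, target: str = "STN") -> "SettingLabel":
        status = "optimal" if distance_mm == 0 else "non_optimal"
        return SettingLabel("contact", status, distance_mm, target=target)

    @staticmethod
    def voltage(voltage_class: str, target: str = "STN") -> "SettingLabel":
        status = "optimal" if voltage_class == "optimal" else "non_optimal"
        offset = {
            "optimal": 0.0,
            "subtherapeutic": SUBTHERAPEUTIC_OFFSET_V,
            "supratherapeutic": SUPRATHERAPEUTIC_OFFSET_V,
        }[voltage_class]
        return SettingLabel(
            "voltage", status, 0.0, voltage_class, offset, target=target
        )


@dataclass(frozen=True)
class EffectTemplate:
    """Per-region signed BOLD amplitude in percent of baseline."""

    amplitudes: dict[str, float]

    def __post_init__(self) -> None:
        for name, amp in self.amplitudes.items():
            if not np.isfinite(amp):
                raise ValueError(f"non-finite amplitude for region {name}")

    def amplitude_map(self, atlas: RoiAtlas) -> np.ndarray:
        unknown = set(self.amplitudes) - set(atlas.names)
        if unknown:
            raise ValueError(f"template regions not in atlas: {sorted(unknown)}")
        out = np.zeros(atlas.labels.shape)
        for name, amp in self.amplitudes.items():
            out[atlas.mask(name)] = amp
        return out


def _optimal_template(base_amp: float, target: str) -> dict[str, float]:
    a = base_amp
    if target == "STN":
        return {"left_m1": -a, "left_thalamus": a, "right_ant_cerebellum": a}
    # GPi variant: pallidal/thalamic emphasis, weaker cortical deactivation
    return {
        "left_pallidum": a,
        "left_thalamus": 0.8 * a,
        "left_m1": -0.5 * a,
        "right_ant_cerebellum": 0.4 * a,
    }


_NORMALIZER_REGIONS = (
    "left_visual",
    "right_visual",
    "left_operculum",
    "right_operculum",
)


def effect_template(setting: SettingLabel, base_amp: float = 1.0) -> EffectTemplate:
    """Deterministic amplitude table for one tested setting.

    Contact at distance d mm: motor amplitudes scaled by max(0, 1 - d/9) and
    side-effect (visual/opercular) regions set to +base * d/9.
    Subtherapeutic voltage: optimal template x 0.4.  Supratherapeutic:
    optimal x 1.3, +0.6*base in the side-effect regions, and +0.5*base in the
    right-hemisphere mirrors of the active optimal regions.
    """
    a = base_amp
    opt = _optimal_template(a, setting.target)
    if setting.mode == "contact":
        d = setting.contact_distance_mm
        scale = max(0.0, 1.0 - d / MAX_DISTANCE_MM)
        amps = {k: v * scale for k, v in opt.items()}
        if d > 0:
            for name in _NORMALIZER_REGIONS:
                amps[name] = a * d / MAX_DISTANCE_MM
        return EffectTemplate(amps)
    if setting.voltage_class == "optimal":
        return EffectTemplate(dict(opt))
    if setting.voltage_class == "subtherapeutic":
        return EffectTemplate({k: 0.4 * v for k, v in opt.items()})
    if setting.voltage_class == "supratherapeutic":
        amps = {k: 1.3 * v for k, v in opt.items()}
        for name in _NORMALIZER_REGIONS:
            amps[name] = amps.get(name, 0.0) + 0.6 * a
        for name in opt:
            hemi, _, role = name.partition("_")
            if hemi == "left":
                mirror = f"right_{role}"
                amps[mirror] = amps.get(mirror, 0.0) + 0.5 * a
        return EffectTemplate(amps)
    raise ValueError(f"unknown setting class {setting!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Temporal noise and motion parameters of the generator.

    ``sigma`` is the AR(1) innovation standard deviation in percent of
    baseline; ``ar1`` the lag-1 autocorrelation; ``drift_amp`` the total
    linear drift over the session (percent); ``spike_prob`` the per-volume
    probability of a motion spike of ``spike_mm`` millimetres (above the
    1.5 mm censoring threshold by default).
    """

    sigma: float = 1.0
    ar1: float = 0.3
    drift_amp: float = 0.5
    spike_prob: float = 0.02
    spike_mm: float = 2.0
    walk_step_mm: float = 0.02
    walk_step_rad: float = 5e-4

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must be in [0, 1)")
        if self.spike_prob < 0 or self.spike_prob > 1:
            raise ValueError("spike_prob must be a probability")


def simulate_run(
    template: EffectTemplate,
    atlas: RoiAtlas,
    paradigm: Paradigm,
    noise: NoiseModel,
    seed,
    baseline: float = 100.0,
    hrf_params: HrfParams | None = None,
    ids: dict | None = None,
) -> tuple[BoldRun, MotionTrace]:
    """Generate one BOLD run plus motion trace, reproducible from ``seed``.

    The task regressor is peak-normalized, so a template amplitude of a%
    produces an a% excursion at the response peak; a noiseless run is
    recovered exactly by the first-level GLM.
    """
    rng = np.random.default_rng(seed)
    n = paradigm.n_volumes
    amp = template.amplitude_map(atlas)
    reg = task_regressor(paradigm, hrf_params)

    signal = 1.0 + amp[..., None] * reg / 100.0
    signal = signal + (noise.drift_amp / 100.0) * np.linspace(-0.5, 0.5, n)
    if noise.sigma > 0:
        eps = rng.standard_normal(atlas.labels.shape + (n,)) * (noise.sigma / 100.0)
        if noise.ar1 > 0:
            eps = lfilter([1.0], [1.0, -noise.ar1], eps, axis=-1)
        signal = signal + eps

    # smooth random-walk motion plus occasional large spikes
    steps = np.empty((n, 6))
    steps[:, :3] = rng.normal(0.0, noise.walk_step_mm, (n, 3))
    steps[:, 3:] = rng.normal(0.0, noise.walk_step_rad, (n, 3))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    spikes = rng.random(n) < noise.spike_prob
    spikes[0] = False
    params[spikes, 0] += noise.spike_mm

    data = baseline * signal
    # spiked volumes get a global intensity glitch (motion artifact proxy)
    data[..., spikes] *= 1.0 + noise.spike_mm / 100.0

    run = BoldRun(data=data, tr_s=paradigm.tr_s, paradigm=paradigm, ids=ids or {})
    return run, MotionTrace(params)


@dataclass(frozen=True)
class CohortSpec:
    """Composition of the default synthetic cohort.

    Mirrors the study layout: 20 contact-mode and 19 voltage-mode training
    patients (a few GPi-targeted), plus two held-out test cohorts of 9
    patients each — one already clinically optimized ("programmed"), one
    stimulation-naive.
    """

    n_contact_train: int = 20
    n_voltage_train: int = 19
    n_test_programmed: int = 9
    n_test_naive: int = 9
    gpi_contact_train: int = 2
    gpi_voltage_train: int = 2
    gpi_test_naive: int = 1
    base_amp: float = 1.0
    amp_jitter: float = 0.2
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    paradigm: Paradigm = field(default_factory=Paradigm)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        for name in (
            "n_contact_train",
            "n_voltage_train",
            "n_test_programmed",
            "n_test_naive",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_train(self) -> int:
        return self.n_contact_train + self.n_voltage_train


def _contact_settings(optimal_index: int, target: str) -> list[SettingLabel]:
    """Settings for a contact-mode patient on a 4-contact, 3 mm pitch lead."""
    out = [SettingLabel.optimal_contact(target)]
    for j in range(4):
        if j != optimal_index:
            out.append(SettingLabel.contact(abs(j - optimal_index) * 3.0, target))
    return out


def _voltage_settings(target: str) -> list[SettingLabel]:
    return [
        SettingLabel.voltage("optimal", target),
        SettingLabel.voltage("subtherapeutic", target),
        SettingLabel.voltage("supratherapeutic", target),
    ]


def cohort_plan(spec: CohortSpec) -> list[dict]:
    """Deterministic patient-by-patient plan (no randomness).

    Contact patients cycle the optimal contact through lead positions 0..3
    and test all four contacts; voltage patients test optimal, sub- and
    supratherapeutic amplitudes.  Test cohorts alternate contact and voltage
    modes.  GPi-targeted patients are the last few of each group.
    """
    plan: list[dict] = []

    def add(cohort, mode, idx, n_total, n_gpi, settings_fn):
        target = "GPi" if idx >= n_total - n_gpi else "STN"
        pid = f"{cohort}_{mode}_{idx:02d}"
        plan.append(
            {
                "patient_id": pid,
                "cohort": cohort,
                "mode": mode,
                "target": target,
                "settings": settings_fn(target),
            }
        )

    for i in range(spec.n_contact_train):
        add(
            "train",
            "contact",
            i,
            spec.n_contact_train,
            spec.gpi_contact_train,
            lambda t, i=i: _contact_settings(i % 4, t),
        )
    for i in range(spec.n_voltage_train):
        add(
            "train",
            "voltage",
            i,
            spec.n_voltage_train,
            spec.gpi_voltage_train,
            _voltage_settings,
        )
    for cohort, n_pat, n_gpi in (
        ("test_programmed", spec.n_test_programmed, 0),
        ("test_naive", spec.n_test_naive, spec.gpi_test_naive),
    ):
        for i in range(n_pat):
            mode = "contact" if i % 2 == 0 else "voltage"
            if mode == "contact":
                add(
                    cohort,
                    mode,
                    i,
                    n_pat,
                    n_gpi,
                    lambda t, i=i: _contact_settings(i % 4, t),
                )
            else:
                add(cohort, mode, i, n_pat, n_gpi, _voltage_settings)
    return plan


def iter_cohort(spec: CohortSpec, seed: int, atlas: RoiAtlas | None = None):
    """Yield (row, BoldRun, MotionTrace) for every run of the cohort.

    Per-patient response amplitudes are jittered (uniform within
    ``1 +/- amp_jitter``) to emulate inter-subject effect-size variability;
    all randomness derives from ``seed``.
    """
    atlas = atlas or make_default_atlas(spec.grid_shape)
    plan = cohort_plan(spec)
    for p_idx, patient in enumerate(plan):
        prng = np.random.default_rng(np.random.SeedSequence([int(seed), p_idx]))
        jitter = 1.0 + spec.amp_jitter * (2.0 * prng.random() - 1.0)
        for r_idx, setting in enumerate(patient["settings"]):
            template = effect_template(setting, spec.base_amp * jitter)
            run_seed = np.random.SeedSequence([int(seed), p_idx, r_idx + 1])
            run_id = f"{patient['patient_id']}_run{r_idx}"
            ids = {"patient_id": patient["patient_id"], "run_id": run_id}
            run, trace = simulate_run(
                template,
                atlas,
                spec.paradigm,
                spec.noise,
                run_seed,
                ids=ids,
            )
            row = {
                "patient_id": patient["patient_id"],
                "run_id": run_id,
                "mode": setting.mode,
                "status": setting.status,
                "contact_distance_mm": setting.contact_distance_mm,
                "voltage_offset_v": setting.voltage_offset_v,
                "target": setting.target,
                "cohort": patient["cohort"],
            }
            yield row, run, trace


def make_cohort(spec: CohortSpec, seed: int, out_dir) -> pd.DataFrame:
    """Write the cohort to disk: gzipped NIfTI runs, motion CSVs, manifest.

    Returns the manifest with relative ``run_path`` / ``motion_path``
    columns.  Volumes are stored as float32.
    """
    from pathlib import Path

    from . import io as _io

    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    atlas = make_default_atlas(spec.grid_shape)
    _io.write_nifti(out / "atlas.nii.gz", atlas.labels.astype(np.int16))
    rows = []
    for row, run, trace in iter_cohort(spec, seed, atlas):
        run_path = f"runs/{row['run_id']}.nii.gz"
        motion_path = f"runs/{row['run_id']}_motion.csv"
        _io.write_nifti(out / run_path, run.data.astype(np.float32))
        pd.DataFrame(
            trace.params, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
        ).to_csv(out / motion_path, index=False)
        rows.append({**row, "run_path": run_path, "motion_path": motion_path})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
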