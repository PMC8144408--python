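"""Per-run voxelwise GLM: smoothing, motion censoring, design, t-maps.

The first-level model regresses every voxel's BOLD time series on the
convolved ON/OFF task regressor plus nuisance terms (six rigid-body motion
parameters, a linear drift, an intercept).  Volumes whose head displacement
relative to the session reference exceeds a threshold (1.5 mm by default)
are removed before fitting.  The contrast of interest is stimulation
ON > OFF; its t statistic is

    t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c)

with sigma2 the residual mean square on df = n_retained - n_columns degrees
of freedom.  Voxels with zero residual variance (possible only on noiseless
synthetic data) receive a signed sentinel of +/-1e9 and are flagged.

No autocorrelation prewhitening is applied; errors are treated as i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import t as _t_dist

from .atlas import RoiAtlas
from .hrf import HrfParams, Paradigm, task_regressor

__all__ = [
    "BoldRun",
    "MotionTrace",
    "DesignMatrix",
    "TMap",
    "T_SENTINEL",
    "smooth_volume",
    "censor_motion",
    "build_design_matrix",
    "fit_glm",
    "threshold_clusters",
    "motion_task_correlation",
    "estimate_empirical_hrf",
    "first_level",
]

T_SENTINEL = 1e9

DESIGN_COLUMNS = (
    "task",
    "motion_tx",
    "motion_ty",
    "motion_tz",
    "motion_rx",
    "motion_ry",
    "motion_rz",
    "drift",
    "intercept",
)


@dataclass
class BoldRun:
    """One 4-D session: (x, y, z, t) data plus timing and identifiers."""

    data: np.ndarray
    tr_s: float
    paradigm: Paradigm
    ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (n_volumes, 6)")
        if not np.isfinite(self.params).all():
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def displacement_mm(self) -> np.ndarray:
        """Euclidean norm of the translation vector relative to volume 0."""
        rel = self.params[:, :3] - self.params[0, :3]
        return np.linalg.norm(rel, axis=1)


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: tuple[str, ...]
    retained: np.ndarray

    @property
    def task_index(self) -> int:
        return self.columns.index("task")


@dataclass
class TMap:
    """Voxelwise ON>OFF t statistics with degrees of freedom."""

    t: np.ndarray
    df: int
    flags: np.ndarray  # True where residual variance was zero (sentinel t)
    contrast: str = "on_gt_off"

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be > 0")


def smooth_volume(vol: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Gaussian smoothing with FWHM given in voxels; fwhm 0 is the identity."""
    if fwhm_vox < 0:
        raise ValueError("fwhm_vox must be >= 0")
    if fwhm_vox == 0:
        return vol
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return ndimage.gaussian_filter(np.asarray(vol, dtype=float), sigma)


def censor_motion(trace: MotionTrace, threshold_mm: float = 1.5) -> np.ndarray:
    """Indices of volumes whose displacement does NOT exceed the threshold.

    Removal uses a strict inequality (displacement > threshold); volumes at
    exactly the threshold are retained.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be > 0")
    disp = trace.displacement_mm()
    retained = np.flatnonzero(disp <= threshold_mm)
    if retained.size == 0:
        raise ValueError("all volumes exceed the motion threshold; run unusable")
    return retained


def _first_dependent_column(X: np.ndarray, columns) -> str:
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            return columns[j]
        rank = r
    return columns[-1]


def build_design_matrix(
    regressor: np.ndarray,
    trace: MotionTrace,
    retained: np.ndarray,
    drift_on: bool = True,
    drop_constant_columns: bool = False,
) -> DesignMatrix:
    """Assemble [task, 6 motion, drift, intercept] restricted to retained rows.

    Motion columns are mean-centered over the retained volumes.  A rank
    deficiency raises an error naming the first offending column unless
    ``drop_constant_columns`` removes constant (typically all-zero motion)
    columns first.
    """
    regressor = np.asarray(regressor, dtype=float)
    n = regressor.size
    if trace.n_volumes != n:
        raise ValueError("motion trace and regressor lengths disagree")
    retained = np.asarray(retained, dtype=int)
    cols = [regressor]
    names = ["task"]
    for j in range(6):
        cols.append(trace.params[:, j])
        names.append(DESIGN_COLUMNS[1 + j])
    if drift_on:
        cols.append(np.linspace(-0.5, 0.5, n))
        names.append("drift")
    cols.append(np.ones(n))
    names.append("intercept")

    X = np.column_stack(cols)[retained]
    # mean-center motion columns on the retained rows
    for j, name in enumerate(names):
        if name.startswith("motion_"):
            X[:, j] = X[:, j] - X[:, j].mean()

    if drop_constant_columns:
        keep = [
            j
            for j, name in enumerate(names)
            if name == "intercept" or np.ptp(X[:, j]) > 0
        ]
        X = X[:, keep]
        names = [names[j] for j in keep]

    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _first_dependent_column(X, names)
        raise ValueError(f"design matrix is rank deficient (column '{bad}')")
    return DesignMatrix(X=X, columns=tuple(names), retained=retained)


def fit_glm(run: BoldRun, design: DesignMatrix) -> TMap:
    """Ordinary least squares per voxel; returns the task-contrast t-map."""
    X = design.X
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("not enough retained volumes for the design")
    shape3 = run.data.shape[:3]
    Y = run.data[..., design.retained].reshape(-1, n).T  # n x V
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ Y)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c = np.zeros(p)
    c[design.task_index] = 1.0
    varfac = float(c @ np.linalg.solve(XtX, c))
    effect = beta[design.task_index]
    zero_var = sigma2 <= np.finfo(float).eps * np.abs(Y).max(initial=1.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(sigma2 * varfac)
    t = np.where(zero_var, np.sign(effect) * T_SENTINEL, t)
    t = np.nan_to_num(t, nan=0.0)
    return TMap(
        t=t.reshape(shape3),
        df=df,
        flags=zero_var.reshape(shape3),
    )


_CONN_STRUCTS = {6: 1, 18: 2, 26: 3}


def threshold_clusters(
    tmap: TMap,
    p_voxel: float = 0.001,
    k_min: int = 50,
    connectivity: int = 26,
) -> tuple[np.ndarray, list[dict]]:
    """Two-sided voxel threshold plus cluster-extent filtering.

    Voxels pass when |t| exceeds the two-sided Student-t quantile for
    ``p_voxel`` at the map's df.  Positive and negative voxels are labeled
    as separate connected components; components smaller than ``k_min``
    voxels are discarded.  Returns the integer label grid (0 = background)
    and a per-cluster summary (label, sign, size).
    """
    if not (0 < p_voxel < 1):
        raise ValueError("p_voxel must be in (0, 1)")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if connectivity not in _CONN_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    thr = _t_dist.ppf(1.0 - p_voxel / 2.0, tmap.df)
    struct = ndimage.generate_binary_structure(3, _CONN_STRUCTS[connectivity])
    out = np.zeros(tmap.t.shape, dtype=np.int32)
    clusters: list[dict] = []
    next_label = 1
    for sign, mask in ((1, tmap.t > thr), (-1, tmap.t < -thr)):
        lab, nlab = ndimage.label(mask, structure=struct)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for comp in range(1, nlab + 1):
            if sizes[comp - 1] >= k_min:
                out[lab == comp] = next_label
                clusters.append(
                    {"label": next_label, "sign": sign, "size": int(sizes[comp - 1])}
                )
                next_label += 1
    return out, clusters


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant input")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def motion_task_correlation(trace: MotionTrace, regressor: np.ndarray) -> np.ndarray:
    """Pearson correlation of each of the 6 motion parameters with the task.

    Used as a diagnostic that the stimulation cycling does not induce
    paradigm-locked head motion.
    """
    regressor = np.asarray(regressor, dtype=float)
    if trace.n_volumes != regressor.size:
        raise ValueError("motion trace and regressor lengths disagree")
    return np.array([_pearson(trace.params[:, j], regressor) for j in range(6)])


def estimate_empirical_hrf(
    run: BoldRun,
    paradigm: Paradigm,
    roi_name: str,
    atlas: RoiAtlas,
    hrf_params: HrfParams | None = None,
) -> tuple[np.ndarray, float]:
    """Epoch-averaged ROI response and its correlation with the canonical model.

    The ROI-mean time series is converted to percent change about its mean,
    windows of one full cycle (ON + OFF) locked to every ON onset are
    averaged, and the result is correlated against the identically
    epoch-averaged canonical task regressor.  A region responding with an
    inverted (deactivation) time course yields a strongly negative r.
    """
    mask = atlas.mask(roi_name)
    if not mask.any():
        raise ValueError(f"ROI {roi_name} is empty")
    ts = run.data[mask].mean(axis=0)
    mean = ts.mean()
    if mean == 0:
        raise ValueError("ROI mean signal is zero; percent change undefined")
    pct = 100.0 * (ts / mean - 1.0)

    win = int(round(2.0 * paradigm.block_s / paradigm.tr_s))
    onsets = [int(round(s / paradigm.tr_s)) for s, _ in paradigm.on_blocks()]
    windows = [pct[o : o + win] for o in onsets if o + win <= pct.size]
    if not windows:
        raise ValueError("no complete ON-locked windows available")
    curve = np.mean(windows, axis=0)

    reg = task_regressor(paradigm, hrf_params)
    model_windows = [reg[o : o + win] for o in onsets if o + win <= reg.size]
    model = np.mean(model_windows, axis=0)
    return curve, _pearson(curve, model)


def first_level(
    run: BoldRun,
    trace: MotionTrace,
    fwhm_vox: float = 1.5,
    threshold_mm: float = 1.5,
    hrf_params: HrfParams | None = None,
    drop_constant_columns: bool = False,
) -> tuple[TMap, dict]:
    """Smooth, censor, build the design, and fit the GLM for one run.

    Returns the t-map and a per-run diagnostics dict (censored volume count
    and motion-task correlations).
    """
    smoothed = np.empty_like(run.data, dtype=float)
    for v in range(run.data.shape[-1]):
        smoothed[..., v] = smooth_volume(run.data[..., v], fwhm_vox)
    srun = BoldRun(
        data=smoothed, tr_s=run.tr_s, paradigm=run.paradigm, ids=dict(run.ids)
    )
    retained = censor_motion(trace, threshold_mm)
    reg = task_regressor(run.paradigm, hrf_params)
    design = build_design_matrix(
        reg, trace, retained, drop_constant_columns=drop_constant_columns
    )
    tmap = fit_glm(srun, design)
    diag = {
        "n_censored": int(run.paradigm.n_volumes - retained.size),
        "motion_task_r": motion_task_correlation(trace, reg).tolist(),
    }
    return tmap, diag
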