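"""First-level GLM: smoothing, censoring, design, t statistics, clusters."""

import numpy as np
import pytest
from scipy.stats import pearsonr, t as t_dist

from dbsfmri import (
    BoldRun,
    DesignMatrix,
    MotionTrace,
    NoiseModel,
    Paradigm,
    SettingLabel,
    build_design_matrix,
    censor_motion,
    effect_template,
    estimate_empirical_hrf,
    fit_glm,
    motion_task_correlation,
    simulate_run,
    smooth_volume,
    task_regressor,
    threshold_clusters,
)
from dbsfmri.glm import T_SENTINEL, TMap


def _trace(n, tx=None):
    params = np.zeros((n, 6))
    if tx is not None:
        params[: len(tx), 0] = tx
    return MotionTrace(params)


def _random_trace(n, rng, scale=0.05):
    return MotionTrace(np.cumsum(rng.normal(0, scale, (n, 6)), axis=0))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        assert smooth_volume(vol, 0.0) is vol

    def test_impulse_response_peaks_at_impulse(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        sm = smooth_volume(vol, 2.0)
        assert np.unravel_index(np.argmax(sm), sm.shape) == (4, 4, 4)
        assert sm.sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), -1.0)


class TestCensoring:
    def test_zero_motion_retains_all(self):
        assert list(censor_motion(_trace(5), 1.5)) == [0, 1, 2, 3, 4]

    def test_printed_example(self):
        trace = _trace(5, tx=[0.0, 0.5, 2.0, 1.4, 1.6])
        assert list(censor_motion(trace, 1.5)) == [0, 1, 3]

    def test_boundary_is_strict(self):
        trace = _trace(4, tx=[0.0, 1.5, 1.5, 1.5])
        assert list(censor_motion(trace, 1.5)) == [0, 1, 2, 3]

    def test_reference_volume_always_retained(self):
        # displacement is measured relative to volume 0, so the session
        # reference itself can never be censored
        trace = _trace(4, tx=[0.0, 9.0, 9.0, 9.0])
        assert list(censor_motion(trace, 0.5)) == [0]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            censor_motion(_trace(3), 0.0)


class TestDesignMatrix:
    def test_default_shape_195_by_9(self, rng):
        p = Paradigm()
        reg = task_regressor(p)
        design = build_design_matrix(
            reg, _random_trace(p.n_volumes, rng), np.arange(p.n_volumes)
        )
        assert design.X.shape == (195, 9)
        assert design.columns[0] == "task"
        assert design.columns[-1] == "intercept"

    def test_zero_motion_is_rank_deficient(self):
        p = Paradigm()
        reg = task_regressor(p)
        with pytest.raises(ValueError, match="motion"):
            build_design_matrix(reg, _trace(p.n_volumes), np.arange(p.n_volumes))

    def test_drop_constant_columns_relaxes(self):
        p = Paradigm()
        reg = task_regressor(p)
        design = build_design_matrix(
            reg, _trace(p.n_volumes), np.arange(p.n_volumes),
            drop_constant_columns=True,
        )
        assert "motion_tx" not in design.columns

    def test_censoring_removes_rows(self, rng):
        p = Paradigm()
        reg = task_regressor(p)
        retained = np.setdiff1d(np.arange(p.n_volumes), [3, 10, 50])
        design = build_design_matrix(reg, _random_trace(p.n_volumes, rng), retained)
        assert design.X.shape[0] == 192


def _toy_design(x):
    X = np.column_stack([x, np.ones(len(x))])
    return DesignMatrix(X=X, columns=("task", "intercept"), retained=np.arange(len(x)))


class TestFitGlm:
    def test_perfect_fit_flagged_with_sentinel(self):
        x = np.array([0.0, 1, 0, 1, 0, 1])
        data = x.reshape(1, 1, 1, -1)
        run = BoldRun(data, 2.0, Paradigm(lead_in_s=2, block_s=2, n_cycles=3, tr_s=2))
        tmap = fit_glm(run, _toy_design(x))
        assert tmap.flags[0, 0, 0]
        assert tmap.t[0, 0, 0] == T_SENTINEL

    def test_toy_t_matches_closed_form_ols(self):
        # hand OLS: beta = Sxy/Sxx, t = beta / sqrt(s2 / Sxx), df = 4
        x = np.array([0.0, 1, 0, 1, 0, 1])
        y = np.array([0.1, 1.2, -0.1, 0.9, 0.0, 1.1])
        xc = x - x.mean()
        beta = (xc @ y) / (xc @ xc)
        resid = y - y.mean() - beta * xc
        s2 = resid @ resid / 4
        t_oracle = beta / np.sqrt(s2 / (xc @ xc))
        run = BoldRun(
            y.reshape(1, 1, 1, -1), 2.0,
            Paradigm(lead_in_s=2, block_s=2, n_cycles=3, tr_s=2),
        )
        tmap = fit_glm(run, _toy_design(x))
        assert tmap.df == 4
        assert tmap.t[0, 0, 0] == pytest.approx(t_oracle, abs=1e-10)

    def test_whole_map_matches_brute_force_voxel_loop(self, rng):
        n = 20
        data = rng.normal(10, 1, size=(5, 5, 5, n))
        X = np.column_stack(
            [rng.normal(size=n), rng.normal(size=n), np.ones(n)]
        )
        design = DesignMatrix(X=X, columns=("task", "nuis", "intercept"),
                              retained=np.arange(n))
        run = BoldRun(data, 2.0, Paradigm(lead_in_s=0, block_s=10, n_cycles=2, tr_s=1))
        tmap = fit_glm(run, design)
        XtXinv = np.linalg.inv(X.T @ X)
        for idx in np.ndindex(5, 5, 5):
            y = data[idx]
            beta = XtXinv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (n - 3)
            t_oracle = beta[0] / np.sqrt(s2 * XtXinv[0, 0])
            assert tmap.t[idx] == pytest.approx(t_oracle, abs=1e-8)

    def test_censored_volumes_never_contribute(self, atlas, rng):
        p = Paradigm()
        tpl = effect_template(SettingLabel.optimal_contact())
        run, trace = simulate_run(tpl, atlas, p, NoiseModel(spike_prob=0.0), seed=1)
        trace.params[[20, 100], 0] = 5.0  # force censoring of two volumes
        retained = censor_motion(trace, 1.5)
        reg = task_regressor(p)
        design = build_design_matrix(reg, trace, retained)
        t1 = fit_glm(run, design).t
        scrambled = run.data.copy()
        scrambled[..., 20], scrambled[..., 100] = (
            run.data[..., 100] * 3.7,
            run.data[..., 20] * -1.2,
        )
        run2 = BoldRun(scrambled, p.tr_s, p)
        t2 = fit_glm(run2, design).t
        np.testing.assert_array_equal(t1, t2)


class TestClusterThresholding:
    def _tmap(self, t):
        return TMap(t=t, df=100, flags=np.zeros(t.shape, bool))

    def test_all_zero_map_has_no_clusters(self):
        labels, clusters = threshold_clusters(self._tmap(np.zeros((10, 10, 10))))
        assert not clusters
        assert labels.max() == 0

    def test_49_voxel_blob_discarded_50_retained(self):
        t = np.zeros((20, 20, 20))
        blob49 = np.zeros_like(t, dtype=bool)
        blob49.ravel()[:0] = False
        t[1:8, 1:8, 1] = 10.0  # 49 voxels
        labels, clusters = threshold_clusters(self._tmap(t), k_min=50)
        assert not clusters
        t[1:8, 1:8, 1] = 0.0
        t[1:6, 1:6, 1:3] = 10.0  # 50 voxels
        labels, clusters = threshold_clusters(self._tmap(t), k_min=50)
        assert [c["size"] for c in clusters] == [50]

    def test_two_disjoint_blobs_two_labels(self):
        t = np.zeros((20, 20, 20))
        t[1:6, 1:5, 1:4] = 8.0  # 60 voxels
        t[10:15, 10:14, 10:13] = -8.0  # 60 voxels, negative
        labels, clusters = threshold_clusters(self._tmap(t), k_min=50)
        assert len(clusters) == 2
        assert sorted(c["sign"] for c in clusters) == [-1, 1]

    def test_retained_clusters_all_supra_threshold_and_large(self, rng):
        t = rng.normal(0, 3, size=(15, 15, 15))
        tmap = self._tmap(t)
        labels, clusters = threshold_clusters(tmap, p_voxel=0.05, k_min=5)
        thr = t_dist.ppf(1 - 0.05 / 2, tmap.df)
        for c in clusters:
            vals = t[labels == c["label"]]
            assert vals.size >= 5
            assert np.all(np.abs(vals) > thr)

    def test_type_i_control_on_white_noise(self, rng):
        # voxelwise false-positive rate at p=0.001 stays near nominal
        n, shape = 60, (8, 8, 8)
        exceed = 0
        total = 0
        p = Paradigm(lead_in_s=20, block_s=10, n_cycles=5, tr_s=2)
        assert p.n_volumes == n
        X = np.column_stack([task_regressor(p), np.ones(n)])
        design = DesignMatrix(X=X, columns=("task", "intercept"),
                              retained=np.arange(n))
        for seed in range(10):
            srng = np.random.default_rng(seed)
            data = srng.normal(0, 1, size=shape + (n,))
            run = BoldRun(data, 2.0, p)
            tmap = fit_glm(run, design)
            thr = t_dist.ppf(1 - 0.001 / 2, tmap.df)
            exceed += int((np.abs(tmap.t) > thr).sum())
            total += tmap.t.size
        assert exceed / total <= 0.005


class TestDiagnostics:
    def test_motion_equal_to_regressor_correlates_fully(self):
        p = Paradigm()
        reg = task_regressor(p)
        params = np.column_stack([reg] * 6)
        r = motion_task_correlation(MotionTrace(params), reg)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_orthogonalized_motion_correlates_zero(self, rng):
        p = Paradigm()
        reg = task_regressor(p)
        regc = reg - reg.mean()
        params = rng.normal(size=(p.n_volumes, 6))
        for j in range(6):
            col = params[:, j] - params[:, j].mean()
            params[:, j] = col - (col @ regc) / (regc @ regc) * regc
        r = motion_task_correlation(MotionTrace(params), reg)
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_random_walk_matches_scipy_pearson(self, rng):
        p = Paradigm()
        reg = task_regressor(p)
        trace = _random_trace(p.n_volumes, rng)
        r = motion_task_correlation(trace, reg)
        for j in range(6):
            assert r[j] == pytest.approx(pearsonr(trace.params[:, j], reg)[0],
                                         abs=1e-12)

    def test_constant_motion_rejected(self):
        p = Paradigm()
        with pytest.raises(ValueError):
            motion_task_correlation(_trace(p.n_volumes), task_regressor(p))


QUIET = NoiseModel(sigma=0.0, ar1=0.0, drift_amp=0.0, spike_prob=0.0,
                   walk_step_mm=0.0, walk_step_rad=0.0)


class TestEmpiricalHrf:
    def _run(self, atlas, amp):
        from dbsfmri.synthetic import EffectTemplate

        tpl = EffectTemplate({"left_thalamus": amp})
        return simulate_run(tpl, atlas, Paradigm(), QUIET, seed=0)[0]

    def test_positive_response_self_match(self, atlas):
        _, r = estimate_empirical_hrf(
            self._run(atlas, 1.0), Paradigm(), "left_thalamus", atlas
        )
        assert r >= 0.99

    def test_deactivation_gives_negative_correlation(self, atlas):
        _, r = estimate_empirical_hrf(
            self._run(atlas, -1.0), Paradigm(), "left_thalamus", atlas
        )
        assert r <= -0.9

    def test_flat_signal_rejected(self, atlas):
        with pytest.raises(ValueError):
            estimate_empirical_hrf(
                self._run(atlas, 0.0), Paradigm(), "left_thalamus", atlas
            )
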