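"""Single-trial Welch coherence and the stimulus-role GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from riftsearch import SimConfig, generate_experiment
from riftsearch.trial_glm import (C_DISTRACTOR, C_TARGET, WelchParams,
                                  assemble_response, behaviour_glm,
                                  build_design, fit_glm, rift_per_role,
                                  single_trial_coherence)


def _trial_frame(conditions, set_sizes=None, rts=None):
    n = len(conditions)
    return pd.DataFrame({
        "trial_index": np.arange(n),
        "condition": conditions,
        "set_size": set_sizes if set_sizes is not None else [32] * n,
        "rt": rts if rts is not None else np.linspace(0.5, 1.0, n),
        "tot": np.arange(n) / max(n - 1, 1),
    })


class TestSingleTrialCoherence:
    def test_nine_windows_in_standard_interval(self):
        assert WelchParams().n_windows(1000.0) == 9

    def test_self_coherence_is_unity(self):
        fs = 1000.0
        time = np.arange(-200, 600) / fs
        x = np.sin(2 * np.pi * 60 * time)[None, :].repeat(4, axis=0)
        coh = single_trial_coherence(x, x, time, fs, 60.0, prefilter=False)
        np.testing.assert_allclose(coh, 1.0, atol=1e-10)

    def test_matches_scipy_welch_oracle(self, rng):
        # independent route: scipy's averaged-cross-spectrum coherence on
        # the identical segmentation of the 0.2-0.5 s interval
        fs = 1000.0
        time = np.arange(-200, 600) / fs
        params = WelchParams()
        ref = np.sin(2 * np.pi * 60 * time)
        x = 0.5 * ref + rng.standard_normal(time.size)
        coh = single_trial_coherence(x[None, None, :], ref[None, :], time, fs,
                                     60.0, params, prefilter=False)
        i0 = np.searchsorted(time, params.interval[0] - 1e-9)
        i1 = np.searchsorted(time, params.interval[1] - 1e-9)
        f, cxy = signal.coherence(x[i0:i1], ref[i0:i1], fs=fs, window="hann",
                                  nperseg=100, noverlap=75, nfft=512,
                                  detrend=False)
        k = params.freq_bin(60.0, fs)
        assert coh[0, 0] == pytest.approx(cxy[k], abs=1e-10)

    def test_tag_bin_off_grid_resolution(self):
        params = WelchParams()
        # 512-point grid at 1000 Hz: 60 Hz -> bin 31 (60.55), 67 -> 34 (66.41)
        assert params.freq_bin(60.0, 1000.0) == 31
        assert params.freq_bin(67.0, 1000.0) == 34

    def test_interval_too_short_rejected(self):
        fs = 1000.0
        time = np.arange(-50, 330) / fs
        x = np.zeros((2, time.size))
        with pytest.raises(ValueError):
            single_trial_coherence(
                x, x[0][None].repeat(2, 0), time, fs, 60.0,
                WelchParams(interval=(0.2, 0.31)), prefilter=False)


class TestDesignMatrix:
    def test_single_guided_trial_rows(self):
        dm = build_design(_trial_frame(["guided"]))
        np.testing.assert_array_equal(dm.X, [[1, 0, 0, 0], [0, 0, 1, 0]])
        assert dm.row_map["role"].tolist() == ["target", "distractor"]

    def test_single_unguided_trial_rows(self):
        dm = build_design(_trial_frame(["unguided"]))
        np.testing.assert_array_equal(dm.X, [[0, 1, 0, 0], [0, 1, 0, 0]])

    def test_mixed_table_column_sums(self):
        conds = ["guided", "unguided", "guided", "unguided", "guided", "guided"]
        dm = build_design(_trial_frame(conds))
        sums = dm.X.sum(axis=0)
        assert sums[0] == 4 and sums[2] == 4      # one T and one D row per guided
        assert sums[1] == 4                        # two U rows per unguided

    def test_indicators_partition_and_forbid_intercept(self):
        dm = build_design(_trial_frame(["guided", "unguided", "guided"]))
        np.testing.assert_array_equal(dm.X[:, :3].sum(axis=1), np.ones(6))
        with_intercept = np.column_stack([np.ones(6), dm.X])
        assert np.linalg.matrix_rank(with_intercept) < 5

    def test_tot_duplicated_across_roles(self):
        trials = _trial_frame(["guided", "guided", "unguided"])
        dm = build_design(trials)
        n = len(trials)
        np.testing.assert_array_equal(dm.X[:n, 3], dm.X[n:, 3])


class TestFitGLM:
    def test_matches_normal_equation_oracle_on_fixture(self):
        # frozen 8-observation fixture (4 trials: G, U, G, U)
        trials = _trial_frame(["guided", "unguided", "guided", "unguided"])
        X = build_design(trials).X
        y = np.array([0.62, 0.41, 0.55, 0.38, 0.22, 0.44, 0.25, 0.40])
        res = fit_glm(y, X)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.betas, beta_oracle, atol=1e-12)
        resid = y - X @ beta_oracle
        sigma2 = resid @ resid / (8 - 4)
        assert res.sigma2 == pytest.approx(sigma2, rel=1e-12)
        for ci, c in enumerate((C_TARGET, C_DISTRACTOR)):
            varcope = c @ np.linalg.inv(X.T @ X) @ c * sigma2
            assert res.cope[ci] == pytest.approx(c @ beta_oracle, abs=1e-12)
            assert res.t[ci] == pytest.approx(
                (c @ beta_oracle) / np.sqrt(varcope), rel=1e-10)

    def test_exact_recovery_flags_undefined_t(self):
        trials = _trial_frame(["guided", "unguided"] * 3)
        X = build_design(trials).X
        b_true = np.array([0.5, 0.3, 0.1, 0.05])
        res = fit_glm(X @ b_true, X)
        np.testing.assert_allclose(res.betas, b_true, atol=1e-12)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-20)
        assert np.isnan(res.t).all()

    def test_t_invariant_to_response_rescaling(self, rng):
        trials = _trial_frame(["guided", "unguided"] * 5)
        X = build_design(trials).X
        y = rng.random(X.shape[0])
        t1 = fit_glm(y, X).t
        t2 = fit_glm(137.0 * y, X).t
        np.testing.assert_allclose(t1, t2, rtol=1e-10)

    def test_null_gains_centre_contrasts_at_zero(self, rng):
        # B_T = B_U = B_D in the generating model: cope distribution
        # centred on 0 across replicates
        trials = _trial_frame(["guided", "unguided"] * 10)
        X = build_design(trials).X
        copes = []
        for _ in range(200):
            y = 0.4 + 0.05 * rng.standard_normal(X.shape[0])
            copes.append(fit_glm(y, X).cope[0])
        mean = np.mean(copes)
        sem = np.std(copes, ddof=1) / np.sqrt(len(copes))
        assert abs(mean) < 3 * sem + 1e-12


class TestRiftPerRole:
    def test_planted_gains_order_role_responses(self, small_experiment):
        rec, trials, *_ = small_experiment
        rift_t, rift_d = rift_per_role(rec, trials)
        guided = (trials["condition"] == "guided").to_numpy()
        sig = [0, 1, 2]
        assert rift_t[np.ix_(sig)][:, guided].mean() > \
            rift_d[np.ix_(sig)][:, guided].mean()

    def test_glm_recovers_effect_directions(self, small_experiment):
        rec, trials, *_ = small_experiment
        rift_t, rift_d = rift_per_role(rec, trials)
        res = fit_glm(assemble_response(rift_t, rift_d), build_design(trials))
        for s in (0, 1, 2):
            assert res.t[0, s] > 2.0    # target boosting
            assert res.t[1, s] < -2.0   # distractor suppression


class TestBehaviourGLM:
    def test_planted_rt_slope_detected(self, rng):
        n = 80
        trials = _trial_frame(["guided"] * n,
                              rts=rng.lognormal(-0.5, 0.3, n) + 0.2)
        y = 0.3 - 0.1 * trials["rt"].to_numpy() \
            + 0.005 * rng.standard_normal(n)
        res = behaviour_glm(y, trials)
        assert res.t[2] < -3.0

    def test_null_rt_effect_centred_at_zero(self, rng):
        n = 60
        ts = []
        for _ in range(100):
            trials = _trial_frame(["guided"] * n,
                                  rts=rng.lognormal(-0.5, 0.3, n) + 0.2)
            y = 0.3 + 0.02 * rng.standard_normal(n)
            ts.append(behaviour_glm(y, trials).t[2])
        assert abs(np.mean(ts)) < 3 / np.sqrt(len(ts))

    def test_constant_response_zeroes_slopes(self, rng):
        trials = _trial_frame(["guided"] * 10,
                              rts=rng.lognormal(-0.5, 0.3, 10) + 0.2)
        res = behaviour_glm(np.full(10, 0.7), trials)
        assert res.betas[1] == pytest.approx(0.0, abs=1e-10)
        assert res.betas[2] == pytest.approx(0.0, abs=1e-10)

    def test_unguided_trials_rejected(self):
        with pytest.raises(ValueError):
            behaviour_glm(np.zeros(4), _trial_frame(["unguided"] * 4))
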