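"""Generator: design structure, determinism, planted spectral content."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from riftsearch import SimConfig, generate_experiment, make_reference
from riftsearch.config import ConfigurationError
from riftsearch.simdata import (build_trial_table, distractor_freq,
                                generate_gaze, generate_layout, target_freq)


class TestTrialTable:
    def test_full_design_has_960_trials(self):
        trials = build_trial_table(SimConfig(), np.random.default_rng(0))
        assert len(trials) == 960
        # 24 blocks x 40 trials, half present per block
        per_block = trials.groupby("block")["target_present"].sum()
        assert (per_block == 20).all()

    def test_colour_frequency_counterbalancing_exact(self):
        trials = build_trial_table(SimConfig(seed=3), np.random.default_rng(3))
        # bijection per trial and exact balance within each block
        assert (trials["freq_yellow"] != trials["freq_cyan"]).all()
        for _, block in trials.groupby("block"):
            n60 = (block["freq_yellow"] == 60.0).sum()
            assert n60 == len(block) // 2

    def test_tot_monotone_and_spans_unit_interval(self):
        trials = build_trial_table(SimConfig(n_blocks=4, trials_per_block=10),
                                   np.random.default_rng(1))
        tot = trials.sort_values("trial_index")["tot"].to_numpy()
        assert tot[0] == 0.0 and tot[-1] == 1.0
        assert (np.diff(tot) >= 0).all()

    def test_guided_target_colour_constant_within_block(self):
        trials = build_trial_table(SimConfig(), np.random.default_rng(2))
        guided = trials[trials["condition"] == "guided"]
        assert (guided.groupby("block")["target_colour"].nunique() == 1).all()
        unguided = trials[trials["condition"] == "unguided"]
        # randomised per trial: essentially every block shows both colours
        assert (unguided.groupby("block")["target_colour"].nunique() == 2).mean() > 0.8

    def test_role_frequencies_partition_tags(self):
        trials = build_trial_table(SimConfig(n_blocks=4), np.random.default_rng(4))
        tf, df = target_freq(trials), distractor_freq(trials)
        assert set(np.unique(tf)) == {60.0, 67.0}
        assert (tf != df).all()

    def test_rt_direction_effects(self):
        trials = build_trial_table(SimConfig(seed=9), np.random.default_rng(9))
        mean_rt = trials.groupby(["condition", "set_size"])["rt"].mean()
        assert mean_rt["unguided", 32] > mean_rt["unguided", 16]
        assert mean_rt["guided", 16] < mean_rt["unguided", 16]


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"tag_freqs": (60.0, 60.0)},
        {"tag_freqs": (60.0, 600.0)},
        {"trials_per_block": 7},
        {"boost_gain": 0.0},
        {"seed": "abc"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)

    def test_json_roundtrip(self, tmp_path):
        cfg = SimConfig(n_blocks=4, snr=0.7, seed=5)
        cfg.to_json(tmp_path / "cfg.json")
        assert SimConfig.from_json(tmp_path / "cfg.json") == cfg


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_blocks=2, trials_per_block=6, n_sensors=3,
                        signal_sensors=(0,), search_duration=0.6, seed=77)
        rec1, t1, l1, g1 = generate_experiment(cfg)
        rec2, t2, l2, g2 = generate_experiment(cfg)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        np.testing.assert_array_equal(rec1.ref, rec2.ref)
        pd.testing.assert_frame_equal(t1, t2)
        np.testing.assert_array_equal(l1[0].positions, l2[0].positions)
        np.testing.assert_array_equal(g1[0].x, g2[0].x)

    def test_different_seed_differs(self):
        cfg = SimConfig(n_blocks=2, trials_per_block=6, n_sensors=3,
                        signal_sensors=(0,), search_duration=0.6, seed=1)
        rec1, *_ = generate_experiment(cfg.replace(seed=1), with_gaze=False)
        rec2, *_ = generate_experiment(cfg.replace(seed=2), with_gaze=False)
        assert not np.array_equal(rec1.data, rec2.data)


class TestReference:
    def test_pure_sine_zero_phase_starts_at_zero(self):
        ref = make_reference(60.0, 0.0, 0.5, 1000.0)
        assert ref[0] == 0.0
        assert np.max(np.abs(ref)) <= 1.0

    def test_noise_amplitude_scales_residual(self, rng):
        clean = make_reference(60.0, 0.3, 2.0, 1000.0)
        noisy = make_reference(60.0, 0.3, 2.0, 1000.0, noise_amplitude=0.05,
                               rng=rng)
        resid = noisy - clean
        assert abs(resid.std() - 0.05) < 0.01

    def test_seeded_calls_identical(self):
        a = make_reference(67.0, 0.1, 1.0, 1000.0, 0.05,
                           rng=np.random.default_rng(5))
        b = make_reference(67.0, 0.1, 1.0, 1000.0, 0.05,
                           rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError):
            make_reference(600.0, 0.0, 1.0, 1000.0)


class TestPlantedSignal:
    def test_tag_power_peaks_at_tag_frequency(self):
        cfg = SimConfig(n_blocks=2, trials_per_block=8, snr=20.0,
                        n_sensors=2, signal_sensors=(0,), evoked_amplitude=0.0,
                        search_duration=0.8, seed=21)
        rec, trials, *_ = generate_experiment(cfg, with_gaze=False)
        sl = rec.time_slice((0.0, 0.8))
        f, pxx = signal.welch(rec.data[0, 0, sl], fs=rec.fs, nperseg=512)
        band = (f > 40) & (f < 90)
        peak = f[band][np.argmax(pxx[band])]
        assert min(abs(peak - 60.0), abs(peak - 67.0)) < 2.0

    def test_snr_zero_leaves_no_locked_component(self):
        cfg = SimConfig(n_blocks=2, trials_per_block=20, snr=0.0,
                        n_sensors=2, signal_sensors=(0,), evoked_amplitude=0.0,
                        search_duration=0.6, seed=22)
        rec, *_ = generate_experiment(cfg, with_gaze=False)
        from riftsearch.coherence import bandpass_analytic, coherence_timecourse
        a = bandpass_analytic(rec.data, rec.fs, 60.0)
        r = bandpass_analytic(rec.ref[0], rec.fs, 60.0)
        coh = coherence_timecourse(a, r)
        sl = rec.time_slice((0.1, 0.5))
        # null coherence for n=40 trials is ~n^(-1/2), far below 0.4
        assert coh[:, sl].mean() < 0.4


class TestLayouts:
    def test_balanced_colours_within_grid(self, rng):
        lay = generate_layout(16, "yellow", True, rng)
        assert lay.set_size == 16
        assert (lay.colours == "yellow").sum() == 8
        assert lay.is_target.sum() == 1
        assert lay.colours[np.argmax(lay.is_target)] == "yellow"
        assert np.all(np.abs(lay.positions) <= 5.0)

    def test_absent_trials_have_no_target(self, rng):
        lay = generate_layout(32, "cyan", False, rng)
        assert lay.is_target.sum() == 0


class TestGazeGenerator:
    def test_pinned_gaze_sits_on_target_colour_stimulus(self, rng):
        lay = generate_layout(16, "cyan", True, rng)
        trace = generate_gaze(lay, 0.7, 1000.0, colour_bias=1.0,
                              jitter_scale=0.0, seed=0)
        targets = lay.positions[lay.colours == "cyan"]
        d = np.hypot(targets[:, 0] - trace.x[0], targets[:, 1] - trace.y[0])
        assert d.min() < 1e-9
        assert np.ptp(trace.x) == 0.0  # no jitter, no drift

    def test_saccades_predominantly_horizontal(self, rng):
        lay = generate_layout(16, "yellow", True, rng)
        xs, ys = [], []
        for i in range(300):
            tr = generate_gaze(lay, 2.0, 500.0, seed=i, jitter_scale=1.0)
            xs.append(tr.x)
            ys.append(tr.y)
        assert np.var(np.concatenate(xs)) > np.var(np.concatenate(ys))

    def test_blink_samples_flagged_invalid(self):
        lay = generate_layout(16, "yellow", True, np.random.default_rng(0))
        tr = generate_gaze(lay, 1.0, 1000.0, seed=4, blink_rate=5.0)
        if tr.blink_events:
            mask = tr.valid_mask()
            onset, offset = tr.blink_events[0]
            i = int((onset + offset) / 2 * tr.fs)
            assert not mask[min(i, tr.n_samples - 1)]

    def test_colour_bias_bounds_enforced(self, rng):
        lay = generate_layout(16, "yellow", True, rng)
        with pytest.raises(ValueError):
            generate_gaze(lay, 0.5, 1000.0, colour_bias=1.5)
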