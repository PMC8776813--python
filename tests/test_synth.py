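"""Simulator: planted waveforms, spatial patterns, noise, kinematics."""

import numpy as np
import pytest
from scipy import signal

import topodecode as td
from topodecode.synth import (
    ConfigurationError,
    DIRECTIONS,
    blink_artifacts,
    draw_reaction_times,
    pink_background,
)


class TestSimulationConfig:
    def test_defaults_match_experiment_design(self):
        cfg = td.SimulationConfig()
        assert cfg.n_subjects == 12
        assert cfg.n_trials == 416
        assert cfg.n_active == 208
        assert cfg.sampling_rate == 1024
        assert cfg.n_channels == 128

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_active": 420},                       # more active than trials
            {"n_active": 206},                       # not divisible by 4
            {"mrcp_peak_amp_passive": -9.0},         # passive stronger than active
            {"inter_trial_gap": 1.0},                # movements too close
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            td.SimulationConfig(**kwargs)


class TestMrcpWaveform:
    def test_zero_before_onset_lead(self):
        t = np.array([-0.5, -0.30001, -0.26])
        w = td.mrcp_waveform(t, onset_lead=0.25, peak_amp=-8.0)
        assert np.all(w == 0)

    def test_peak_just_after_movement_onset(self):
        t = np.linspace(-1, 1.5, 5000)
        w = td.mrcp_waveform(t, onset_lead=0.25, peak_amp=-8.0)
        t_min = t[np.argmin(w)]
        assert 0 < t_min <= 0.1
        assert np.isclose(w.min(), -8.0, atol=1e-3)

    def test_monotone_ramp_and_recovery(self):
        t = np.linspace(-0.25, 0.05, 400)
        assert np.all(np.diff(td.mrcp_waveform(t, 0.25, -8.0)) <= 1e-12)
        t = np.linspace(0.05, 1.0, 400)
        assert np.all(np.diff(td.mrcp_waveform(t, 0.25, -8.0)) >= -1e-12)

    def test_amplitude_scales_linearly(self):
        t = np.linspace(-0.5, 1.2, 700)
        w8 = td.mrcp_waveform(t, 0.25, -8.0)
        w4 = td.mrcp_waveform(t, 0.25, -4.0)
        assert np.all(w8 <= w4 + 1e-12)
        assert np.allclose(w8, 2 * w4)

    def test_nonnegative_peak_rejected(self):
        with pytest.raises(ValueError):
            td.mrcp_waveform(np.zeros(3), 0.25, peak_amp=1.0)


class TestSpatialPattern:
    def test_unit_gain_at_center(self, layout):
        g = td.spatial_pattern(layout, "D18", spread=0.5)
        assert g[layout.index("D18")] == 1.0
        assert g.min() >= 0 and g.max() == 1.0

    def test_uniform_limit_at_large_spread(self, layout):
        g = td.spatial_pattern(layout, "A1", spread=1e6)
        assert np.allclose(g, 1.0, atol=1e-6)

    def test_contralateral_laterality(self, layout):
        # rightward movement -> left-hemisphere pattern dominates the left
        g = td.spatial_pattern(layout, "D18", spread=0.5, laterality="left")
        left = [i for i, h in enumerate(layout.hemispheres) if h == "left"]
        right = [i for i, h in enumerate(layout.hemispheres) if h == "right"]
        assert g[left].sum() > g[right].sum()
        g_mirror = td.spatial_pattern(layout, "D18", spread=0.5, laterality="right")
        assert g_mirror[right].sum() > g_mirror[left].sum()

    def test_unknown_sensor_rejected(self, layout):
        with pytest.raises(KeyError):
            td.spatial_pattern(layout, "Z99", spread=0.5)


class TestBackgroundAndArtifacts:
    def test_zero_blink_rate_has_no_transients(self):
        cfg = td.SimulationConfig(blink_rate=0.0)
        noise = blink_artifacts(128, 4096, cfg, seed=0)
        assert np.all(noise == 0)

    def test_pink_spectrum_slope(self):
        # least-squares fit to the averaged log-log periodogram over 1-40 Hz
        cfg = td.SimulationConfig(noise_amp=10.0)
        fs = cfg.sampling_rate
        x = pink_background(8, int(60 * fs), cfg, seed=2)
        f, p = signal.welch(x, fs=fs, nperseg=8192, axis=1)
        band = (f >= 1.0) & (f <= 40.0)
        slope = np.polyfit(np.log(f[band]), np.log(p[:, band].mean(axis=0)), 1)[0]
        assert abs(slope - (-1.0)) < 0.3

    def test_blink_energy_peaks_frontally(self, layout):
        cfg = td.SimulationConfig(noise_amp=0.0, blink_rate=30.0)
        art = blink_artifacts(128, int(60 * cfg.sampling_rate), cfg, seed=3, layout=layout)
        energy = (art**2).sum(axis=1)
        assert layout.names[int(np.argmax(energy))] == cfg.blink_center
        frontal = [layout.index(s) for s in layout.frontal()]
        other = [i for i in range(128) if i not in frontal]
        assert energy[frontal].mean() > 5 * energy[other].mean()

    def test_combined_output_shape_and_finiteness(self, layout):
        cfg = td.SimulationConfig()
        both = td.background_and_artifacts(128, 2048, cfg, seed=9, layout=layout)
        assert both.shape == (128, 2048)
        assert np.all(np.isfinite(both))


class TestReactionTimes:
    def test_outlier_fraction_matches_configuration(self):
        dist = td.RTDistribution()
        rng = np.random.default_rng(0)
        rts = draw_reaction_times(10_000, dist, rng)
        lo, hi = dist.bounds
        frac = np.mean((rts < lo) | (rts > hi))
        # 95% binomial interval around 0.02 at n=10000
        se = np.sqrt(0.02 * 0.98 / 10_000)
        assert abs(frac - dist.outlier_prob) < 1.96 * se + 1e-9

    def test_retained_rts_are_bimodal_around_the_modes(self):
        dist = td.RTDistribution()
        rng = np.random.default_rng(1)
        rts = draw_reaction_times(4000, dist, rng)
        kept = rts[(rts >= 0.15) & (rts <= 0.8)]
        fast = kept[kept < 0.4]
        slow = kept[kept >= 0.4]
        assert 0.2 < np.median(fast) < 0.32
        assert 0.45 < np.median(slow) < 0.65


class TestTrialKinematics:
    def test_threshold_recovery_equals_true_rt(self):
        cfg = td.SimulationConfig()
        for rt in (0.2, 0.35, 0.6):
            trace, onset = td.draw_trial_kinematics(rt, "up", cfg)
            detected = int(np.argmax(trace.velocity >= cfg.onset_velocity_threshold))
            assert abs(detected - round(rt * cfg.sampling_rate)) <= 1
            assert onset == round(rt * cfg.sampling_rate)

    @pytest.mark.parametrize("direction,axis,sign", [
        ("left", 0, -1), ("right", 0, 1), ("up", 1, 1), ("down", 1, -1),
    ])
    def test_displacement_follows_direction(self, direction, axis, sign):
        cfg = td.SimulationConfig()
        trace, onset = td.draw_trial_kinematics(0.3, direction, cfg)
        fs = cfg.sampling_rate
        # peak displacement during the outgoing stroke
        i = onset + int(cfg.movement_duration * fs)
        assert sign * trace.position_xy[axis, i] > 0.01

    def test_velocity_consistent_with_position(self):
        cfg = td.SimulationConfig()
        trace, _ = td.draw_trial_kinematics(0.3, "right", cfg)
        d = np.gradient(trace.position_xy, axis=1) * trace.sampling_rate
        speed = np.hypot(d[0], d[1])
        assert np.abs(speed - trace.velocity).max() < 0.02  # m/s


class TestSimulateSubject:
    def test_trial_counts_and_balance(self, small_recording, small_config):
        ev = small_recording.events
        assert len(ev) == small_config.n_trials
        assert (ev["mode"] == "active").sum() == small_config.n_active
        active_dirs = ev.loc[ev["mode"] == "active", "direction"].value_counts()
        assert set(active_dirs.index) == set(DIRECTIONS)
        assert active_dirs.nunique() == 1  # balanced

    def test_events_ordered_and_inside_recording(self, small_recording):
        ev = small_recording.events
        assert (ev["movement_onset_sample"] > ev["stimulus_sample"]).all()
        assert ev["stimulus_sample"].is_monotonic_increasing
        assert ev["movement_onset_sample"].iloc[-1] < small_recording.n_samples
        assert np.all(np.isfinite(small_recording.eeg))

    def test_same_seed_is_bitwise_identical(self, small_config, small_recording):
        again = td.simulate_subject(small_config, "S01", seed=7)
        assert np.array_equal(small_recording.eeg, again.eeg)
        assert np.array_equal(
            small_recording.kinematics.position_xy, again.kinematics.position_xy
        )
        assert small_recording.events.equals(again.events)

    def test_noise_free_recording_equals_planted_sum(self, noise_free_recording):
        assert np.array_equal(
            noise_free_recording.eeg, noise_free_recording.clean_eeg
        )

    def test_active_mrcp_stronger_than_passive(self, noise_free_recording):
        """Class-signal ordering at the planted peak, motor channel."""
        rec = noise_free_recording
        lay = td.biosemi128_layout()
        ch = lay.index("D18")
        fs = rec.sampling_rate
        peaks = {"active": [], "passive": []}
        for _, ev in rec.events.iterrows():
            onset = int(ev["movement_onset_sample"])
            seg = rec.clean_eeg[ch, onset : onset + int(0.1 * fs)]
            peaks[ev["mode"]].append(seg.min())
        assert np.mean(peaks["active"]) < np.mean(peaks["passive"]) < 0

    def test_experiment_generates_all_subjects(self):
        cfg = td.SimulationConfig(
            n_subjects=3, n_trials=8, n_active=4, inter_trial_gap=2.0
        )
        recs = td.simulate_experiment(cfg)
        assert [r.subject_id for r in recs] == ["S01", "S02", "S03"]
        assert len({r.eeg.tobytes() for r in recs}) == 3  # subjects differ
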