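"""Preprocessing chain: filtering, ICA cleanup, RT labelling, epoching."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import topodecode as td
from topodecode.preprocess import (
    DatasetError,
    DegenerateRTError,
    IcaConvergenceError,
)


def _tone(freqs, fs=1024.0, dur=40.0, n_channels=2):
    t = np.arange(int(dur * fs)) / fs
    sig = np.zeros_like(t)
    for f in freqs:
        sig = sig + np.sin(2 * np.pi * f * t)
    eeg = np.tile(sig, (n_channels, 1)).astype(np.float32)
    events = pd.DataFrame(
        {
            "stimulus_sample": [int(2 * fs)],
            "movement_onset_sample": [int(2.3 * fs)],
            "mode": ["active"],
            "direction": ["left"],
            "true_rt": [0.3],
        }
    )
    kin = td.KinematicsTrace(np.zeros((2, eeg.shape[1])), np.zeros(eeg.shape[1]), fs)
    return td.SubjectRecording("T", eeg, fs, events, kin)


def _dft_amplitude(x, f, fs):
    """Single-bin discrete Fourier amplitude (oracle for filter gain)."""
    n = x.size
    k = np.exp(-2j * np.pi * f * np.arange(n) / fs)
    return 2 * abs(x @ k) / n


class TestBandpass:
    def test_default_band(self):
        assert td.PreprocConfig().band == (0.1, 40.0)

    def test_dc_rejection(self):
        rec = _tone([], dur=40.0)
        rec.eeg += 50.0
        out = td.bandpass(rec, (0.1, 40.0))
        assert np.abs(out.eeg.mean()) < 0.5  # < 1% of the 50 uV offset

    def test_passband_and_stopband_gains(self):
        rec = _tone([10.0, 60.0])
        out = td.bandpass(rec, (0.1, 40.0))
        x = out.eeg[0][int(5 * 1024) : int(35 * 1024)]  # avoid edges
        gain10 = _dft_amplitude(x, 10.0, 1024.0)
        gain60 = _dft_amplitude(x, 60.0, 1024.0)
        assert 0.95 <= gain10 <= 1.05
        assert gain60 < 0.1  # >= 20 dB attenuation

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            td.bandpass(_tone([10.0], dur=5.0), (0.1, 600.0))

    def test_events_untouched(self, small_recording, small_bandpassed):
        assert small_bandpassed.events is small_recording.events
        assert small_bandpassed.eeg.shape == small_recording.eeg.shape


class TestIcaClean:
    def test_blink_free_recording_unchanged(self):
        cfg = td.SimulationConfig(
            n_trials=16, n_active=8, blink_rate=0.0, inter_trial_gap=2.0
        )
        rec = td.bandpass(td.simulate_subject(cfg, "S", seed=5), (0.1, 40.0))
        pc = td.PreprocConfig(ica_n_components=8)
        cleaned, report = td.ica_clean(rec, pc)
        assert report["removed"] == []
        assert np.abs(cleaned.eeg - rec.eeg).max() < 1e-6

    def test_cleanup_restores_blink_free_signal(self, small_recording, small_bandpassed):
        pc = td.PreprocConfig()
        cleaned, report = td.ica_clean(small_bandpassed, pc)
        assert 1 <= len(report["removed"]) <= pc.ica_n_components
        blink_free = td.bandpass(
            dataclasses.replace(
                small_recording,
                eeg=small_recording.eeg - small_recording.blink_eeg,
            ),
            (0.1, 40.0),
        )
        lay = td.biosemi128_layout()

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return float(a @ b / np.sqrt((a @ a) * (b @ b)))

        for sensor in lay.frontal()[:3]:
            i = lay.index(sensor)
            before = corr(small_bandpassed.eeg[i], blink_free.eeg[i])
            after = corr(cleaned.eeg[i], blink_free.eeg[i])
            assert after > before

    def test_nonconvergence_raises_in_strict_mode(self, small_bandpassed):
        pc = td.PreprocConfig(
            ica_max_iter=2, ica_tol=1e-12, ica_nonconvergence="raise"
        )
        with pytest.raises(IcaConvergenceError) as err:
            td.ica_clean(small_bandpassed, pc)
        assert err.value.n_iter >= 2


class TestReactionTimeLabelling:
    def _events(self, rts, fs=100.0):
        stim = (np.arange(len(rts)) * 5 * fs + fs).astype(int)
        onset = stim + (np.asarray(rts) * fs).round().astype(int)
        v = np.zeros(int(stim[-1] + 3 * fs))
        for o in onset:
            v[o : o + 20] = 1.0
        events = pd.DataFrame(
            {
                "stimulus_sample": stim,
                "movement_onset_sample": onset,
                "mode": ["active"] * len(rts),
                "direction": ["up"] * len(rts),
                "true_rt": rts,
            }
        )
        kin = td.KinematicsTrace(np.zeros((2, v.size)), v, fs)
        return events, kin

    def test_median_split_hand_example(self):
        events, kin = self._events([0.10, 0.30, 0.50, 0.90])
        res = td.compute_and_label_rt(events, kin, td.PreprocConfig())
        assert list(res.retained) == [False, True, True, False]
        assert res.threshold == pytest.approx(0.40)
        assert list(res.labels) == [-1, 0, 1, -1]  # fast, slow
        assert list(res.reasons) == ["outlier", "", "", "outlier"]

    def test_identical_rts_raise_degenerate_error(self):
        events, kin = self._events([0.3, 0.3, 0.3])
        with pytest.raises(DegenerateRTError):
            td.compute_and_label_rt(events, kin, td.PreprocConfig())

    def test_missing_onset_masked_with_reason(self):
        events, kin = self._events([0.3, 0.4, 0.6])
        # erase the crossing of the second trial only
        o = int(events["movement_onset_sample"].iloc[1])
        kin.velocity[o : o + 30] = 0.0
        res = td.compute_and_label_rt(events, kin, td.PreprocConfig())
        assert res.reasons[1] == "no_onset"
        assert np.isnan(res.rt[1])
        assert list(res.retained) == [True, False, True]

    def test_simulator_ground_truth_recovered(self, small_recording):
        res = td.compute_and_label_rt(
            small_recording.events, small_recording.kinematics, td.PreprocConfig()
        )
        fs = small_recording.sampling_rate
        err = np.abs(res.rt - small_recording.events["true_rt"].to_numpy())
        assert np.nanmax(err) * fs <= 1.0


class TestEpoching:
    def test_rate_shape_and_moments(self, small_bandpassed):
        epochs, kept = td.epoch_normalize_resample(
            small_bandpassed, small_bandpassed.events, (-0.5, 0.5), 250.0
        )
        assert epochs.sampling_rate == 250.0
        assert epochs.trials.shape[1:] == (128, 250)
        assert len(kept) == len(small_bandpassed.events)
        assert np.abs(epochs.trials.mean(axis=2)).max() < 1e-6
        assert np.abs(epochs.trials.std(axis=2) - 1).max() < 1e-5

    def test_rt_window_gives_125_samples(self, small_bandpassed):
        epochs, _ = td.epoch_normalize_resample(
            small_bandpassed, small_bandpassed.events, (-0.5, 0.0), 250.0
        )
        assert epochs.trials.shape[2] == 125

    def test_edge_trials_dropped(self, small_bandpassed):
        events = small_bandpassed.events.copy()
        events.loc[0, "movement_onset_sample"] = 10  # window exceeds the edge
        epochs, kept = td.epoch_normalize_resample(
            small_bandpassed, events, (-0.5, 0.5), 250.0
        )
        assert 0 not in kept
        assert len(kept) == len(events) - 1

    def test_zscore_order_insensitive_for_band_limited_signals(self, small_bandpassed):
        """Guard for z-scoring after (rather than before) resampling."""
        rec = small_bandpassed
        fs = rec.sampling_rate
        onset = int(rec.events["movement_onset_sample"].iloc[2])
        cut = rec.eeg[:, onset - 512 : onset + 512].astype(np.float64)
        from scipy.signal import resample_poly

        a = resample_poly(cut, 125, 512, axis=1)
        a = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
        z = (cut - cut.mean(axis=1, keepdims=True)) / cut.std(axis=1, keepdims=True)
        b = resample_poly(z, 125, 512, axis=1)
        # away from the polyphase edge ripple the two orders agree to a
        # fraction of a percent of the signal scale
        assert np.abs(a - b)[:, 12:-12].max() < 0.05
        assert np.abs(b.std(axis=1) - 1).max() < 0.01


class TestBuildDatasets:
    def test_composition_reduced_scale(self, small_bandpassed, small_config):
        ds = td.build_datasets(small_bandpassed, td.PreprocConfig())
        assert ds["mode"].K == 2
        assert ds["mode"].class_counts().tolist() == [
            small_config.n_active,
            small_config.n_trials - small_config.n_active,
        ]
        assert ds["direction"].K == 4
        assert len(ds["direction"]) <= small_config.n_active
        assert sorted(set(ds["direction"].labels)) == [0, 1, 2, 3]
        assert ds["rt"].K == 2
        assert set(ds["rt"].labels) <= {0, 1}

    def test_rt_subset_fraction_controls_size(self, small_bandpassed):
        full = td.build_datasets(
            small_bandpassed, td.PreprocConfig(rt_subset_fraction=1.0)
        )
        half = td.build_datasets(
            small_bandpassed, td.PreprocConfig(rt_subset_fraction=0.5)
        )
        assert len(half["rt"]) == round(0.5 * len(full["rt"]))

    def test_no_trial_leaks_between_tasks(self, small_bandpassed):
        """Each task draws from its own trial subset exactly once."""
        ds = td.build_datasets(small_bandpassed, td.PreprocConfig())
        n_events = len(small_bandpassed.events)
        n_active = (small_bandpassed.events["mode"] == "active").sum()
        assert len(ds["mode"]) == n_events
        assert len(ds["direction"]) == n_active
        assert len(ds["rt"]) <= n_active

    def test_label_recovery_on_noise_free_data(self, noise_free_recording):
        ds = td.build_datasets(noise_free_recording, td.PreprocConfig())
        ev = noise_free_recording.events
        modes = (ev["mode"] == "passive").astype(int).to_numpy()
        assert np.array_equal(ds["mode"].labels, modes)
        dirs = ev.loc[ev["mode"] == "active", "direction"]
        expected = [("left", "right", "up", "down").index(d) for d in dirs]
        assert np.array_equal(ds["direction"].labels, expected)

    def test_empty_class_raises_named_error(self, noise_free_recording):
        events = noise_free_recording.events.copy()
        events["mode"] = "active"  # no passive trials survive
        rec = dataclasses.replace(noise_free_recording, events=events)
        with pytest.raises(DatasetError, match="passive"):
            td.build_datasets(rec, td.PreprocConfig())
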