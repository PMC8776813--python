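"""Synthetic multi-subject EEG reaching experiments.

Emulates a goal-directed planar reaching study: 12 subjects, 128-channel
EEG at 1024 Hz, 416 trials each (208 self-executed "active", 208
robot-guided "passive"; targets in 4 orthogonal directions),
synchronously recorded cursor kinematics.  Each trial carries a planted
movement-related cortical potential (MRCP): a slow negative wave that
starts ~0.25 s before movement onset, peaks just after it and recovers
to baseline, spatially weighted over a motor-region sensor
neighbourhood contralateral to the moving (right) arm.  Class structure:

* active trials receive a larger-magnitude MRCP than passive ones;
* trials with slower reaction times build the ramp up later
  (``rt_timing_gain``), so pre-movement epochs carry RT information;
* each movement direction adds an execution-locked component over its
  own (contralateral for left/right) sensor neighbourhood.

On top of the planted components the recordings carry 1/f ("pink")
background noise per channel and stereotyped frontal blink artifacts,
so the preprocessing chain (bandpass, ICA blink removal) has realistic
work to do.  All randomness flows from a single integer seed; identical
(config, seed) pairs produce bitwise-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import SensorLayout, biosemi128_layout

__all__ = [
    "SimulationConfig",
    "RTDistribution",
    "KinematicsTrace",
    "SubjectRecording",
    "ConfigurationError",
    "mrcp_waveform",
    "spatial_pattern",
    "background_and_artifacts",
    "pink_background",
    "blink_artifacts",
    "draw_reaction_times",
    "draw_trial_kinematics",
    "simulate_subject",
    "simulate_experiment",
]

DIRECTIONS = ("left", "right", "up", "down")

#: unit target vectors, x toward subject's right, y away from the body
_DIRECTION_VECTORS = {
    "left": np.array([-1.0, 0.0]),
    "right": np.array([1.0, 0.0]),
    "up": np.array([0.0, 1.0]),
    "down": np.array([0.0, -1.0]),
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class RTDistribution:
    """Two-component lognormal reaction-time mixture with outliers.

    Non-outlier draws come from an equal-weight mixture of a fast
    (median ``fast_median``) and a slow (median ``slow_median``)
    lognormal mode, truncated to ``bounds`` by redraw so that exactly
    ``outlier_prob`` of trials fall outside ``bounds`` in expectation;
    outliers are drawn uniformly just outside the bounds.
    """

    fast_median: float = 0.25
    slow_median: float = 0.55
    sigma: float = 0.18
    fast_weight: float = 0.5
    outlier_prob: float = 0.02
    bounds: tuple[float, float] = (0.15, 0.8)

    @property
    def mean(self) -> float:
        """Mean of the (untruncated) non-outlier mixture."""
        m = np.exp(self.sigma**2 / 2)
        return (
            self.fast_weight * self.fast_median
            + (1 - self.fast_weight) * self.slow_median
        ) * m


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic reaching experiment.

    Amplitudes are in microvolts, times in seconds, rates in Hz unless
    stated otherwise.
    """

    n_subjects: int = 12
    n_trials: int = 416
    n_active: int = 208
    sampling_rate: float = 1024.0
    n_channels: int = 128
    # planted MRCP
    mrcp_onset_lead: float = 0.25
    mrcp_peak_delay: float = 0.05
    mrcp_recovery_time: float = 1.0
    mrcp_peak_amp_active: float = -8.0
    mrcp_peak_amp_passive: float = -4.0
    direction_amp: float = -5.0
    spatial_spread: float = 0.5
    motor_center: str = "D18"        # left-hemisphere motor region (~C3)
    midline_front_center: str = "C23"  # ~FCz, 'up' movements
    midline_back_center: str = "A3"    # ~CPz, 'down' movements
    rt_timing_gain: float = 0.3      # s of extra ramp lead per s of RT deficit
    subject_amp_sd: float = 0.15     # lognormal sd of per-subject scaling
    trial_amp_sd: float = 0.10       # lognormal sd of per-trial scaling
    # noise and artifacts
    noise_amp: float = 10.0          # RMS of 1/f background, per channel
    blink_rate: float = 15.0         # blinks per minute
    blink_amp: float = 80.0
    blink_center: str = "C18"        # ~Fpz
    # behaviour
    rt_distribution: RTDistribution = field(default_factory=RTDistribution)
    inter_trial_gap: float = 2.5     # movement-onset to next stimulus, >= 2
    gap_jitter: float = 0.3
    peak_speed: float = 0.35         # m/s
    movement_duration: float = 0.6   # s, full bell width
    onset_velocity_threshold: float = 0.05  # m/s, defines movement onset
    rt_subset_fraction: float = 0.5  # fraction of retained active trials in RT set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active > self.n_trials:
            raise ConfigurationError("n_active cannot exceed n_trials")
        if self.n_active % 4:
            raise ConfigurationError(
                "n_active must be divisible by 4 for balanced directions"
            )
        if abs(self.mrcp_peak_amp_passive) >= abs(self.mrcp_peak_amp_active):
            raise ConfigurationError(
                "passive MRCP magnitude must be below the active one"
            )
        if self.inter_trial_gap < 2.0:
            raise ConfigurationError("successive movements must be >= 2 s apart")
        if self.n_trials < 1 or self.n_channels < 1:
            raise ConfigurationError("need at least one trial and one channel")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")


@dataclass
class KinematicsTrace:
    """Planar cursor trajectory synchronized with the EEG."""

    position_xy: np.ndarray  # (2, n_samples), meters
    velocity: np.ndarray     # (n_samples,), m/s (speed)
    sampling_rate: float

    def __post_init__(self) -> None:
        self.position_xy = np.asarray(self.position_xy, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.position_xy.shape != (2, self.velocity.size):
            raise ValueError("position and velocity lengths disagree")


@dataclass
class SubjectRecording:
    """Continuous EEG + events + kinematics for one subject."""

    subject_id: str
    eeg: np.ndarray            # (n_channels, n_samples), microvolts
    sampling_rate: float
    events: pd.DataFrame       # stimulus_sample, movement_onset_sample, mode, direction, true_rt
    kinematics: KinematicsTrace
    layout_name: str = "biosemi128"
    clean_eeg: np.ndarray | None = None  # simulator ground truth (no noise/blinks)
    blink_eeg: np.ndarray | None = None  # simulator ground truth: blink part only

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.eeg)):
            raise ValueError("EEG contains non-finite values")
        ev = self.events
        if (ev["movement_onset_sample"] <= ev["stimulus_sample"]).any():
            raise ValueError("movement onset must follow the stimulus")
        if (ev["movement_onset_sample"] >= self.n_samples).any():
            raise ValueError("an event lies outside the recording")


# ---------------------------------------------------------------------------
# primitive generators


def mrcp_waveform(
    time_axis: np.ndarray,
    onset_lead: float = 0.25,
    peak_amp: float = -8.0,
    recovery_time: float = 1.0,
    peak_delay: float = 0.05,
) -> np.ndarray:
    """Movement-related cortical potential template.

    Zero before ``-onset_lead``, a monotone negative cosine ramp down to
    ``peak_amp`` at ``peak_delay`` (just after movement onset, t = 0),
    then a monotone cosine recovery back to baseline at
    ``recovery_time``.  ``time_axis`` is in seconds relative to
    movement onset.
    """
    if onset_lead <= 0:
        raise ValueError("onset_lead must be positive")
    if peak_amp >= 0:
        raise ValueError("peak_amp must be negative")
    if recovery_time <= peak_delay:
        raise ValueError("recovery_time must exceed peak_delay")
    t = np.asarray(time_axis, dtype=float)
    out = np.zeros_like(t)
    ramp = (t >= -onset_lead) & (t <= peak_delay)
    out[ramp] = peak_amp * 0.5 * (
        1 - np.cos(np.pi * (t[ramp] + onset_lead) / (onset_lead + peak_delay))
    )
    rec = (t > peak_delay) & (t <= recovery_time)
    out[rec] = peak_amp * 0.5 * (
        1 + np.cos(np.pi * (t[rec] - peak_delay) / (recovery_time - peak_delay))
    )
    return out


def spatial_pattern(
    layout: SensorLayout,
    region_center: str,
    spread: float = 0.5,
    laterality: str = "none",
) -> np.ndarray:
    """Per-sensor gain of a smooth scalp patch.

    A Gaussian bump in layout coordinates, gain 1 at the sensor nearest
    the (possibly mirrored) centre, decaying with layout distance.
    ``laterality`` forces the centre into the named hemisphere by
    mirroring it across the midline when needed.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    center = layout.position(region_center).copy()
    if laterality not in ("left", "right", "none"):
        raise ValueError(f"unknown laterality {laterality!r}")
    if laterality == "left" and center[0] > 0:
        center[0] = -center[0]
    elif laterality == "right" and center[0] < 0:
        center[0] = -center[0]
    d2 = np.sum((layout.positions - center) ** 2, axis=1)
    gains = np.exp(-d2 / (2.0 * spread**2))
    return gains / gains.max()


def _blink_shape(fs: float, tau: float = 0.08, duration: float = 0.5) -> np.ndarray:
    """Unit-amplitude blink transient (gamma-like positive deflection)."""
    t = np.arange(int(round(duration * fs))) / fs
    w = (t / tau) * np.exp(1.0 - t / tau)
    return w


def pink_background(
    n_channels: int, n_samples: int, config: SimulationConfig, seed: int
) -> np.ndarray:
    """Per-channel 1/f ("pink") background noise.

    White noise shaped in the frequency domain to a 1/f power spectrum
    (flattened below 0.5 Hz to keep finite power), scaled to
    ``config.noise_amp`` RMS per channel.
    """
    if n_channels < 1 or n_samples < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    out = np.zeros((n_channels, n_samples), dtype=np.float32)
    if config.noise_amp <= 0:
        return out
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    knee = 0.5
    shaping = 1.0 / np.sqrt(np.maximum(freqs, knee))
    shaping[0] = 0.0  # no DC
    for ch in range(n_channels):
        spec = (
            rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        ) * shaping
        x = np.fft.irfft(spec, n=n_samples)
        rms = np.sqrt(np.mean(x**2))
        if rms > 0:
            out[ch] = (config.noise_amp / rms) * x
    return out


def blink_artifacts(
    n_channels: int,
    n_samples: int,
    config: SimulationConfig,
    seed: int,
    layout: SensorLayout | None = None,
) -> np.ndarray:
    """Stereotyped ocular transients, maximal over frontal sensors.

    Blink events arrive as a Poisson process at ``config.blink_rate``
    per minute; each is a gamma-shaped positive deflection of about
    ``config.blink_amp`` microvolts at the frontal pole, decaying over
    the scalp with the standard frontal spatial pattern.
    """
    if n_channels < 1 or n_samples < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    out = np.zeros((n_channels, n_samples), dtype=np.float32)
    if config.blink_rate <= 0 or config.blink_amp == 0:
        return out
    if layout is None:
        layout = biosemi128_layout()
    if len(layout) != n_channels:
        raise ValueError("layout size must match n_channels")
    gains = spatial_pattern(
        layout, config.blink_center, spread=0.45, laterality="none"
    ).astype(np.float32)
    duration_min = n_samples / fs / 60.0
    n_blinks = rng.poisson(config.blink_rate * duration_min)
    shape = _blink_shape(fs).astype(np.float32)
    starts = rng.integers(0, max(1, n_samples - shape.size), size=n_blinks)
    for s in np.sort(starts):
        amp = config.blink_amp * rng.lognormal(0.0, 0.2)
        seg = slice(s, s + shape.size)
        out[:, seg] += np.float32(amp) * gains[:, None] * shape[None, :]
    return out


def background_and_artifacts(
    n_channels: int,
    n_samples: int,
    config: SimulationConfig,
    seed: int,
    layout: SensorLayout | None = None,
) -> np.ndarray:
    """1/f background plus frontal blink transients (their sum)."""
    s_bg, s_blink = np.random.SeedSequence(seed).generate_state(2, np.uint32)
    out = pink_background(n_channels, n_samples, config, int(s_bg))
    out += blink_artifacts(n_channels, n_samples, config, int(s_blink), layout=layout)
    return out


def draw_reaction_times(
    n: int, dist: RTDistribution, rng: np.random.Generator
) -> np.ndarray:
    """Sample reaction times from the mixture-with-outliers model."""
    lo, hi = dist.bounds
    out = np.empty(n)
    is_outlier = rng.random(n) < dist.outlier_prob
    for i in range(n):
        if is_outlier[i]:
            # uniformly just outside the retention bounds, 2:1 slow:fast
            if rng.random() < 1 / 3:
                out[i] = rng.uniform(0.05, lo - 1e-3)
            else:
                out[i] = rng.uniform(hi + 1e-3, hi + 0.35)
        else:
            while True:
                median = (
                    dist.fast_median
                    if rng.random() < dist.fast_weight
                    else dist.slow_median
                )
                rt = median * np.exp(dist.sigma * rng.standard_normal())
                if lo <= rt <= hi:
                    out[i] = rt
                    break
    return out


def _speed_profile(config: SimulationConfig) -> tuple[np.ndarray, int]:
    """Sampled bell speed profile and the index of its threshold crossing."""
    fs = config.sampling_rate
    n = int(round(config.movement_duration * fs))
    s = np.arange(n) / fs
    v = config.peak_speed * 0.5 * (
        1 - np.cos(2 * np.pi * s / config.movement_duration)
    )
    cross = int(np.argmax(v >= config.onset_velocity_threshold))
    return v, cross


def draw_trial_kinematics(
    true_rt: float,
    direction: str,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[KinematicsTrace, int]:
    """Cursor kinematics for a single trial, stimulus at local t = 0.

    The speed stays below the onset threshold until ``stimulus +
    true_rt``, then follows a bell profile toward the target; a return
    stroke brings the cursor back afterwards.  Returns the trace and
    the movement-onset sample (first threshold crossing), which equals
    ``round(true_rt * fs)`` by construction.
    """
    if true_rt <= 0:
        raise ValueError("true_rt must be positive")
    fs = config.sampling_rate
    profile, cross = _speed_profile(config)
    onset = int(round(true_rt * fs))
    start = onset - cross
    total = start + profile.size + int(0.2 * fs) + profile.size + int(0.2 * fs)
    vx = np.zeros(total)
    vy = np.zeros(total)
    u = _DIRECTION_VECTORS[direction]
    vx[start : start + profile.size] = u[0] * profile
    vy[start : start + profile.size] = u[1] * profile
    ret = start + profile.size + int(0.2 * fs)
    vx[ret : ret + profile.size] = -u[0] * profile
    vy[ret : ret + profile.size] = -u[1] * profile
    pos = np.cumsum(np.vstack([vx, vy]), axis=1) / fs
    speed = np.hypot(vx, vy)
    return KinematicsTrace(pos, speed, fs), onset


# ---------------------------------------------------------------------------
# whole-subject simulation


def _assign_conditions(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomly interleaved mode and direction labels, balanced."""
    n, na = config.n_trials, config.n_active
    modes = np.array(["active"] * na + ["passive"] * (n - na))
    dirs = np.empty(n, dtype=object)
    dirs[:na] = np.repeat(DIRECTIONS, na // 4)
    # passive directions: round-robin (balance not required, kept tidy)
    dirs[na:] = [DIRECTIONS[i % 4] for i in range(n - na)]
    order = rng.permutation(n)
    return pd.DataFrame({"mode": modes[order], "direction": dirs[order]})


def simulate_subject(
    config: SimulationConfig,
    subject_id: str,
    seed: int,
    store_clean: bool = False,
) -> SubjectRecording:
    """Generate one subject's synchronized EEG + kinematics recording.

    ``store_clean`` additionally keeps the noise- and artifact-free
    planted component sum (ground truth for cleanup benchmarks).
    """
    fs = config.sampling_rate
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    layout = biosemi128_layout()
    if config.n_channels != len(layout):
        raise ConfigurationError(
            f"simulator requires the {len(layout)}-sensor layout"
        )

    cond = _assign_conditions(config, rng)
    n = config.n_trials
    active = cond["mode"].to_numpy() == "active"
    rts = np.empty(n)
    rts[active] = draw_reaction_times(int(active.sum()), config.rt_distribution, rng)
    rts[~active] = 0.35 * np.exp(0.1 * rng.standard_normal(int((~active).sum())))

    # schedule: movement onsets separated by >= inter_trial_gap
    stim_samples = np.empty(n, dtype=np.int64)
    onset_samples = np.empty(n, dtype=np.int64)
    t_cursor = 2.0
    for i in range(n):
        stim_samples[i] = int(round(t_cursor * fs))
        onset_samples[i] = stim_samples[i] + int(round(rts[i] * fs))
        t_cursor = (
            onset_samples[i] / fs
            + config.inter_trial_gap
            + rng.uniform(0.0, config.gap_jitter)
        )
    n_samples = int(onset_samples[-1] + round(2.0 * fs))

    events = pd.DataFrame(
        {
            "stimulus_sample": stim_samples,
            "movement_onset_sample": onset_samples,
            "mode": cond["mode"].to_numpy(),
            "direction": cond["direction"].to_numpy(),
            "true_rt": rts,
        }
    )

    # --- kinematics ------------------------------------------------------
    profile, cross = _speed_profile(config)
    vx = np.zeros(n_samples)
    vy = np.zeros(n_samples)
    gap = int(0.2 * fs)
    for i in range(n):
        u = _DIRECTION_VECTORS[events["direction"].iloc[i]]
        start = int(onset_samples[i]) - cross
        seg = slice(start, start + profile.size)
        vx[seg] += u[0] * profile
        vy[seg] += u[1] * profile
        ret = start + profile.size + gap
        vx[ret : ret + profile.size] -= u[0] * profile
        vy[ret : ret + profile.size] -= u[1] * profile
    position = np.cumsum(np.vstack([vx, vy]), axis=1) / fs
    kinematics = KinematicsTrace(position, np.hypot(vx, vy), fs)

    # --- planted EEG components -----------------------------------------
    clean = np.zeros((config.n_channels, n_samples), dtype=np.float32)
    subject_scale = rng.lognormal(0.0, config.subject_amp_sd)

    g_mode = spatial_pattern(
        layout, config.motor_center, config.spatial_spread, laterality="left"
    ).astype(np.float32)
    g_dir = {
        "left": spatial_pattern(
            layout, config.motor_center, config.spatial_spread, laterality="right"
        ),
        "right": spatial_pattern(
            layout, config.motor_center, config.spatial_spread, laterality="left"
        ),
        "up": spatial_pattern(
            layout, config.midline_front_center, config.spatial_spread
        ),
        "down": spatial_pattern(
            layout, config.midline_back_center, config.spatial_spread
        ),
    }
    g_dir = {k: v.astype(np.float32) for k, v in g_dir.items()}

    rt_ref = config.rt_distribution.mean
    dir_dur = 0.8
    dir_peak = 0.3
    for i in range(n):
        onset = int(onset_samples[i])
        is_active = events["mode"].iloc[i] == "active"
        amp = (
            config.mrcp_peak_amp_active
            if is_active
            else config.mrcp_peak_amp_passive
        )
        trial_scale = rng.lognormal(0.0, config.trial_amp_sd)
        lead = config.mrcp_onset_lead
        if is_active:
            lead = max(
                0.08, lead + config.rt_timing_gain * (rt_ref - rts[i])
            )
        t0 = onset - int(round(lead * fs))
        t1 = onset + int(round(config.mrcp_recovery_time * fs)) + 1
        tt = (np.arange(t0, t1) - onset) / fs
        wave = mrcp_waveform(
            tt,
            onset_lead=lead,
            peak_amp=amp * subject_scale * trial_scale,
            recovery_time=config.mrcp_recovery_time,
            peak_delay=config.mrcp_peak_delay,
        ).astype(np.float32)
        clean[:, t0:t1] += g_mode[:, None] * wave[None, :]

        # execution-locked, direction-specific component (Hann bump)
        d0 = onset
        nd = int(round(dir_dur * fs))
        s = np.arange(nd) / fs
        bump = (
            config.direction_amp
            * subject_scale
            * trial_scale
            * np.sin(np.pi * s / dir_dur) ** 2
            * np.exp(-((s - dir_peak) ** 2) / (2 * 0.2**2))
        ).astype(np.float32)
        gd = g_dir[events["direction"].iloc[i]]
        clean[:, d0 : d0 + nd] += gd[:, None] * bump[None, :]

    noise_seed = int(
        np.random.SeedSequence((seed, 202)).generate_state(1, np.uint32)[0]
    )
    s_bg, s_blink = np.random.SeedSequence(noise_seed).generate_state(2, np.uint32)
    blinks = blink_artifacts(
        config.n_channels, n_samples, config, int(s_blink), layout=layout
    )
    if store_clean:
        eeg = clean + pink_background(
            config.n_channels, n_samples, config, int(s_bg)
        )
        eeg += blinks
    else:
        # build in place to keep the peak working set at two arrays
        eeg = clean
        clean = None
        eeg += pink_background(config.n_channels, n_samples, config, int(s_bg))
        eeg += blinks
        blinks = None

    rec = SubjectRecording(
        subject_id=subject_id,
        eeg=eeg,
        sampling_rate=fs,
        events=events,
        kinematics=kinematics,
        layout_name="biosemi128",
        clean_eeg=clean if store_clean else None,
        blink_eeg=blinks if store_clean else None,
    )
    rec.validate()
    return rec


def simulate_experiment(
    config: SimulationConfig, store_clean: bool = False
) -> list[SubjectRecording]:
    """Simulate all ``config.n_subjects`` subjects of the experiment."""
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_subjects, np.uint32
    )
    return [
        simulate_subject(
            config, f"S{i + 1:02d}", int(seeds[i]), store_clean=store_clean
        )
        for i in range(config.n_subjects)
    ]
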