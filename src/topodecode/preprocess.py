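"""Preprocessing and labelling chain for continuous recordings.

The chain mirrors standard practice for slow-potential decoding:
zero-phase FIR bandpass (0.1-40 Hz), ICA-based ocular cleanup, movement
-onset detection from the cursor velocity, reaction-time (RT)
discretization by a per-subject median split, epoching relative to
movement onset, polyphase resampling to 250 Hz and per-channel
z-normalization of every trial.  From one recording three labelled
datasets are assembled:

* ``mode`` - active vs. passive movement, all trials, 2 classes;
* ``direction`` - left/right/up/down, active trials only, 4 classes;
* ``rt`` - fast vs. slow reaction, a labelled subset of retained
  active trials, 2 classes.

Trials are z-scored after resampling so each channel of each output
trial has exactly zero mean and unit variance; for the band-limited
signals involved the two orders differ negligibly (guarded by a test).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .layout import biosemi128_layout
from .synth import KinematicsTrace, SubjectRecording

__all__ = [
    "PreprocConfig",
    "LabelledEpochSet",
    "RTResult",
    "IcaConvergenceError",
    "DegenerateRTError",
    "DatasetError",
    "bandpass",
    "ica_clean",
    "compute_and_label_rt",
    "epoch_normalize_resample",
    "build_datasets",
    "preprocess_subject",
]

TASK_CLASSES = {
    "mode": ("active", "passive"),
    "direction": ("left", "right", "up", "down"),
    "rt": ("fast", "slow"),
}


class IcaConvergenceError(RuntimeError):
    """FastICA did not converge; carries the iteration count."""

    def __init__(self, n_iter: int, max_iter: int):
        self.n_iter = n_iter
        super().__init__(
            f"ICA failed to converge after {n_iter} iterations (cap {max_iter})"
        )


class DegenerateRTError(ValueError):
    """All retained reaction times are identical; no median split exists."""


class DatasetError(ValueError):
    """A labelled dataset could not be assembled."""


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the preprocessing and labelling chain."""

    band: tuple[float, float] = (0.1, 40.0)
    ica_n_components: int = 16
    blink_corr_threshold: float = 0.7
    velocity_threshold: float = 0.05       # m/s
    rt_bounds: tuple[float, float] = (0.15, 0.8)
    rt_search_window: float = 1.5          # s after stimulus to look for onset
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "rt": (-0.5, 0.0),
            "mode": (-0.5, 0.5),
            "direction": (-0.5, 1.5),
        }
    )
    target_rate: float = 250.0
    rt_subset_fraction: float = 0.5
    rt_subset_seed: int = 0
    ica_seed: int = 0
    ica_max_iter: int = 200
    ica_tol: float = 1e-3
    ica_nonconvergence: str = "warn"       # or "raise"
    ica_fit_samples: int = 100_000         # decimation target for the ICA fit

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_rate / 2):
            raise ValueError(
                "band must satisfy 0 < low < high < target_rate / 2"
            )
        for task, (w0, w1) in self.windows.items():
            if not (w0 < 0 and w0 < w1):
                raise ValueError(
                    f"window for {task!r} must start before t=0 and end after it starts"
                )
        if not 0 < self.rt_subset_fraction <= 1:
            raise ValueError("rt_subset_fraction must be in (0, 1]")


@dataclass
class LabelledEpochSet:
    """Epoched, preprocessed, labelled trials for one task and subject."""

    trials: np.ndarray                 # (n, n_channels, T), z-scored
    labels: np.ndarray                 # (n,), ints in {0..K-1}
    K: int
    class_names: tuple[str, ...]
    channel_names: tuple[str, ...]
    subject_id: str
    sampling_rate: float
    window: tuple[float, float]
    task: str

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.trials) != len(self.labels):
            raise ValueError("trial count and label count disagree")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise ValueError("labels must lie in {0..K-1}")
        if len(self.class_names) != self.K:
            raise ValueError("need one class name per class")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def times(self) -> np.ndarray:
        """Trial time axis in seconds relative to movement onset."""
        n = self.trials.shape[2]
        return self.window[0] + np.arange(n) / self.sampling_rate

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


@dataclass
class RTResult:
    """Per-trial reaction times and their fast/slow discretization."""

    rt: np.ndarray                # (n_trials,), NaN where undetected
    labels: np.ndarray            # (n_trials,), 0=fast, 1=slow, -1 masked
    retained: np.ndarray          # (n_trials,) bool
    threshold: float              # per-subject median of retained RTs
    reasons: np.ndarray           # (n_trials,) object: "", "no_onset", "outlier"


# ---------------------------------------------------------------------------
# filtering and cleanup


def bandpass(
    recording: SubjectRecording, band: tuple[float, float] = (0.1, 40.0)
) -> SubjectRecording:
    """Zero-phase FIR bandpass of the continuous EEG.

    Uses a windowed linear-phase FIR applied forwards via FFT with
    delay compensation (MNE's default overlap-add filter), so the
    output is effectively zero phase.  Events and kinematics pass
    through untouched.
    """
    import mne

    low, high = band
    nyq = recording.sampling_rate / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} invalid for fs={recording.sampling_rate}")
    filtered = np.empty_like(recording.eeg)
    # filter in channel blocks to bound the float64 working set
    for s in range(0, recording.n_channels, 16):
        filtered[s : s + 16] = mne.filter.filter_data(
            recording.eeg[s : s + 16].astype(np.float64),
            sfreq=recording.sampling_rate,
            l_freq=low,
            h_freq=high,
            verbose="error",
        ).astype(recording.eeg.dtype)
    return _dc_replace(recording, eeg=filtered)


def ica_clean(
    recording: SubjectRecording, config: PreprocConfig = PreprocConfig()
) -> tuple[SubjectRecording, dict]:
    """Remove blink components found by ICA from the recording.

    FastICA is fit on a temporally decimated copy of the (already
    bandpassed) EEG.  Components whose time-course correlation
    magnitude with the frontal-channel average exceeds
    ``blink_corr_threshold`` are subtracted from the data via their
    back-projection; everything else is left intact (the cleanup is a
    rank-limited subtraction, not a rank-limited reconstruction).
    """
    from sklearn.decomposition import FastICA

    eeg = recording.eeg  # channels x samples
    n_samples = eeg.shape[1]
    decim = max(1, int(np.ceil(n_samples / config.ica_fit_samples)))
    ica = FastICA(
        n_components=config.ica_n_components,
        whiten="unit-variance",
        max_iter=config.ica_max_iter,
        tol=config.ica_tol,
        random_state=config.ica_seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(eeg[:, ::decim].T.astype(np.float64))
    converged = ica.n_iter_ < config.ica_max_iter
    if not converged:
        # near-Gaussian background components have no stable rotation, so
        # the fixed-point iteration may hit the cap even though the heavy
        # -tailed artifact components it is used for are well resolved
        if config.ica_nonconvergence == "raise":
            raise IcaConvergenceError(ica.n_iter_, config.ica_max_iter)
        warnings.warn(
            f"ICA hit the iteration cap ({ica.n_iter_}); proceeding with the "
            "current unmixing estimate",
            RuntimeWarning,
        )

    # unmix the full recording in sample blocks (bounded working set)
    comp = ica.components_  # (n_components, n_channels)
    mean = ica.mean_[:, None]
    n_comp = comp.shape[0]
    sources = np.empty((n_comp, n_samples))
    step = 200_000
    for s in range(0, n_samples, step):
        sources[:, s : s + step] = comp @ (
            eeg[:, s : s + step].astype(np.float64) - mean
        )

    layout = biosemi128_layout()
    frontal_idx = [layout.index(s) for s in layout.frontal()]
    frontal_avg = eeg[frontal_idx].mean(axis=0).astype(np.float64)
    fa = frontal_avg - frontal_avg.mean()
    fa_norm = np.linalg.norm(fa)
    corrs = np.zeros(n_comp)
    if fa_norm > 0:
        for k in range(n_comp):
            s = sources[k] - sources[k].mean()
            denom = np.linalg.norm(s) * fa_norm
            corrs[k] = float(s @ fa / denom) if denom > 0 else 0.0
    bad = np.flatnonzero(np.abs(corrs) > config.blink_corr_threshold)

    cleaned = eeg.copy()
    if bad.size:
        mixing_bad = ica.mixing_[:, bad]  # (n_channels, n_bad)
        for s in range(0, n_samples, step):
            cleaned[:, s : s + step] -= (
                mixing_bad @ sources[bad, s : s + step]
            ).astype(cleaned.dtype)
    report = {
        "removed": bad.tolist(),
        "correlations": corrs.tolist(),
        "n_iter": int(ica.n_iter_),
        "converged": converged,
        "decimation": decim,
    }
    return _dc_replace(recording, eeg=cleaned), report


# ---------------------------------------------------------------------------
# reaction times


def compute_and_label_rt(
    events: pd.DataFrame,
    kinematics: KinematicsTrace,
    config: PreprocConfig = PreprocConfig(),
) -> RTResult:
    """Detect movement onsets, compute RTs and split them fast/slow.

    RT is the delay between stimulus onset and the first sample at
    which the cursor speed reaches ``velocity_threshold``.  Trials with
    no crossing, or with RT outside ``rt_bounds``, are masked out.  The
    per-subject threshold is the median of the retained RTs; a trial is
    ``fast`` iff its RT falls strictly below it.
    """
    fs = kinematics.sampling_rate
    n = len(events)
    rt = np.full(n, np.nan)
    reasons = np.array([""] * n, dtype=object)
    search = int(round(config.rt_search_window * fs))
    v = kinematics.velocity
    for i in range(n):
        s0 = int(events["stimulus_sample"].iloc[i])
        s1 = min(s0 + search, v.size)
        seg = v[s0:s1]
        hits = np.flatnonzero(seg >= config.velocity_threshold)
        if hits.size == 0:
            reasons[i] = "no_onset"
            continue
        rt[i] = hits[0] / fs
    lo, hi = config.rt_bounds
    with np.errstate(invalid="ignore"):
        outlier = (rt < lo) | (rt > hi)
    reasons[outlier & (reasons == "")] = "outlier"
    retained = np.isfinite(rt) & ~outlier
    if not retained.any():
        raise DegenerateRTError("no retained reaction times")
    kept = rt[retained]
    if np.ptp(kept) == 0:
        raise DegenerateRTError(
            "all retained reaction times are identical; no split possible"
        )
    threshold = float(np.median(kept))
    labels = np.full(n, -1, dtype=int)
    labels[retained] = (rt[retained] >= threshold).astype(int)  # 0 fast, 1 slow
    return RTResult(rt, labels, retained, threshold, reasons)


# ---------------------------------------------------------------------------
# epoching


def epoch_normalize_resample(
    recording: SubjectRecording,
    events: pd.DataFrame,
    window: tuple[float, float],
    target_rate: float = 250.0,
) -> tuple["LabelledEpochSet", np.ndarray]:
    """Cut trials around movement onset, resample and z-score them.

    Returns the epoch set (labels all zero; attach task labels
    afterwards) and the indices of events that survived the recording
    -boundary check.  Resampling is polyphase with anti-aliasing;
    z-scoring is per channel, per trial, over time, applied last so the
    output moments are exact.
    """
    fs = recording.sampling_rate
    w0, w1 = window
    i0 = int(round(w0 * fs))
    i1 = int(round(w1 * fs))
    n_in = i1 - i0
    kept = []
    for i in range(len(events)):
        onset = int(events["movement_onset_sample"].iloc[i])
        if onset + i0 < 0 or onset + i1 > recording.n_samples:
            continue
        kept.append(i)
    kept = np.asarray(kept, dtype=int)
    trials = np.empty((kept.size, recording.n_channels, n_in), dtype=np.float32)
    for j, i in enumerate(kept):
        onset = int(events["movement_onset_sample"].iloc[i])
        trials[j] = recording.eeg[:, onset + i0 : onset + i1]

    frac = Fraction(target_rate / fs).limit_denominator(10_000)
    if frac != 1:
        trials = signal.resample_poly(
            trials, frac.numerator, frac.denominator, axis=2
        )

    trials = trials.astype(np.float64)  # small after resampling
    mean = trials.mean(axis=2, keepdims=True)
    sd = trials.std(axis=2, keepdims=True)
    sd[sd == 0] = 1.0
    trials = (trials - mean) / sd

    layout_names = biosemi128_layout().names
    channel_names = (
        layout_names
        if recording.n_channels == len(layout_names)
        else tuple(f"ch{i}" for i in range(recording.n_channels))
    )
    epochs = LabelledEpochSet(
        trials=trials.astype(np.float32),
        labels=np.zeros(kept.size, dtype=int),
        K=1,
        class_names=("unlabelled",),
        channel_names=channel_names,
        subject_id=recording.subject_id,
        sampling_rate=float(target_rate),
        window=window,
        task="",
    )
    return epochs, kept


def _labelled_subset(
    epochs: LabelledEpochSet,
    kept: np.ndarray,
    event_rows: np.ndarray,
    labels_by_event: dict[int, int],
    task: str,
) -> LabelledEpochSet:
    """Select epochs whose event index has a label and attach labels."""
    sel = [j for j, ev in enumerate(kept) if ev in labels_by_event]
    if not sel:
        raise DatasetError(f"no labelled trials left for task {task!r}")
    class_names = TASK_CLASSES[task]
    labels = np.array([labels_by_event[kept[j]] for j in sel], dtype=int)
    out = LabelledEpochSet(
        trials=epochs.trials[sel],
        labels=labels,
        K=len(class_names),
        class_names=class_names,
        channel_names=epochs.channel_names,
        subject_id=epochs.subject_id,
        sampling_rate=epochs.sampling_rate,
        window=epochs.window,
        task=task,
    )
    counts = out.class_counts()
    if (counts == 0).any():
        empty = [class_names[k] for k in np.flatnonzero(counts == 0)]
        raise DatasetError(f"empty class(es) {empty} in task {task!r}")
    return out


def build_datasets(
    recording: SubjectRecording,
    config: PreprocConfig = PreprocConfig(),
    rt_result: RTResult | None = None,
) -> dict[str, LabelledEpochSet]:
    """Assemble the mode, direction and RT datasets for one subject.

    ``recording`` should already be bandpassed and cleaned.  The RT
    dataset uses a seeded random fraction (``rt_subset_fraction``) of
    the retained active trials, reflecting that concurrent reaction
    labels are typically available for only part of an experiment.
    """
    events = recording.events
    modes = events["mode"].to_numpy()
    dirs = events["direction"].to_numpy()
    mode_labels = {
        i: TASK_CLASSES["mode"].index(m) for i, m in enumerate(modes)
    }
    dir_labels = {
        i: TASK_CLASSES["direction"].index(d)
        for i, d in enumerate(dirs)
        if modes[i] == "active"
    }
    # reaction time is only defined for self-initiated movements: the
    # fast/slow split is computed on the active trials alone
    active_idx = np.flatnonzero(modes == "active")
    if rt_result is None:
        rt_result = compute_and_label_rt(
            events.iloc[active_idx], recording.kinematics, config
        )
    active_retained = active_idx[rt_result.retained]
    labels_by_active = dict(zip(active_idx, rt_result.labels))
    rng = np.random.default_rng(config.rt_subset_seed)
    n_sub = int(round(config.rt_subset_fraction * active_retained.size))
    subset = rng.choice(active_retained, size=n_sub, replace=False)
    rt_labels = {int(i): int(labels_by_active[i]) for i in np.sort(subset)}

    datasets = {}
    for task, labels_by_event in (
        ("mode", mode_labels),
        ("direction", dir_labels),
        ("rt", rt_labels),
    ):
        epochs, kept = epoch_normalize_resample(
            recording, events, config.windows[task], config.target_rate
        )
        datasets[task] = _labelled_subset(
            epochs, kept, kept, labels_by_event, task
        )
    return datasets


def preprocess_subject(
    recording: SubjectRecording,
    config: PreprocConfig = PreprocConfig(),
    run_ica: bool = True,
) -> tuple[dict[str, LabelledEpochSet], dict]:
    """Full chain: bandpass -> ICA cleanup -> labelled datasets."""
    rec = bandpass(recording, config.band)
    report = {}
    if run_ica:
        rec, report = ica_clean(rec, config)
    datasets = build_datasets(rec, config)
    return datasets, report
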