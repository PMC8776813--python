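"""ERP-level statistics: cluster permutation tests, MRCP, linear baseline.

`cluster_test` is a nonparametric spatiotemporal cluster permutation
test in the Maris-Oostenveld style: a pointwise two-sample t statistic
is thresholded at ``point_alpha`` (two-sided), suprathreshold points
are grouped into clusters connected through sensor adjacency and
temporal contiguity, each cluster is scored by its summed t ("cluster
mass"), and cluster masses are referred to the permutation null of the
maximum cluster mass obtained under random relabelling of trials.
P-values use the add-one rule p = (1 + #{null >= observed}) /
(n_permutations + 1), so they are positive multiples of
1/(n_permutations + 1).

`mrcp` computes the movement-related cortical potential: the 1-4 Hz
band of the trial-averaged waveform per channel, with onset detection
(first sustained excursion below -k baseline standard deviations) and
the post-onset negative peak.

`baseline_logistic` is the flattened-epoch linear reference model
evaluated leave-one-subject-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, signal, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ClusterTestResult",
    "MRCPResult",
    "cluster_test",
    "mrcp",
    "baseline_logistic",
]


class DataError(ValueError):
    """Input data cannot support the requested analysis."""


@dataclass
class ClusterTestResult:
    """Spatiotemporal clusters of significant condition differences."""

    clusters: list[np.ndarray]      # boolean (n_channels, n_times) masks
    cluster_stats: np.ndarray       # summed t per cluster (signed)
    p_values: np.ndarray
    n_permutations: int
    point_alpha: float
    cluster_alpha: float
    t_obs: np.ndarray               # (n_channels, n_times)
    t_threshold: float
    null_max: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[int]:
        return [i for i, p in enumerate(self.p_values) if p < self.cluster_alpha]


def _as_trials(x) -> np.ndarray:
    arr = getattr(x, "trials", x)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3:
        raise DataError("expected (n_trials, n_channels, n_times) data")
    return arr


def _spatiotemporal_graph(adjacency: np.ndarray, n_times: int) -> sparse.csr_matrix:
    """Graph over (channel, time) nodes: spatial edges at equal time,
    temporal edges between consecutive samples of one channel."""
    n_ch = adjacency.shape[0]
    a_sp = sparse.csr_matrix(np.asarray(adjacency, dtype=bool))
    eye_t = sparse.eye(n_times, dtype=bool, format="csr")
    chain = sparse.diags([True] * (n_times - 1), 1, shape=(n_times, n_times), dtype=bool)
    chain = (chain + chain.T).tocsr()
    graph = sparse.kron(a_sp, eye_t, format="csr") + sparse.kron(
        sparse.eye(n_ch, dtype=bool, format="csr"), chain, format="csr"
    )
    return graph.tocsr()


def _cluster_masses(
    t_flat: np.ndarray, thresh: float, graph: sparse.csr_matrix
) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected suprathreshold clusters (both signs) and their masses."""
    clusters: list[np.ndarray] = []
    masses: list[float] = []
    for sign in (1.0, -1.0):
        nodes = np.flatnonzero(sign * t_flat > thresh)
        if nodes.size == 0:
            continue
        sub = graph[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for k in range(n_comp):
            members = nodes[labels == k]
            clusters.append(members)
            masses.append(float(t_flat[members].sum()))
    return clusters, np.asarray(masses)


def _max_cluster_mass(
    t_flat: np.ndarray, thresh: float, graph: sparse.csr_matrix
) -> float:
    _, masses = _cluster_masses(t_flat, thresh, graph)
    return float(np.max(np.abs(masses))) if masses.size else 0.0


def _pooled_t(
    s1: np.ndarray, q1: np.ndarray, s_tot: np.ndarray, q_tot: np.ndarray,
    n1: int, n2: int,
) -> np.ndarray:
    """Two-sample pooled-variance t from group-1 and total sums/squares."""
    m1 = s1 / n1
    m2 = (s_tot - s1) / n2
    ss1 = q1 - n1 * m1**2
    ss2 = (q_tot - q1) - n2 * m2**2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(np.maximum(sp2 * (1.0 / n1 + 1.0 / n2), 1e-300))
    return (m1 - m2) / denom


def cluster_test(
    cond_a,
    cond_b,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    point_alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    _perm_chunk: int = 200,
) -> ClusterTestResult:
    """Two-sided spatiotemporal cluster permutation test.

    ``cond_a``/``cond_b`` are `LabelledEpochSet`s or
    ``(n, channels, times)`` arrays on a common channel/time base;
    ``adjacency`` is a symmetric boolean channel-by-channel matrix.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    xa, xb = _as_trials(cond_a), _as_trials(cond_b)
    if xa.shape[1:] != xb.shape[1:]:
        raise DataError("conditions must share channels and time base")
    n1, n2 = len(xa), len(xb)
    if n1 < 2 or n2 < 2:
        raise DataError("need at least 2 trials per condition")
    n_ch, n_t = xa.shape[1:]
    if adjacency.shape != (n_ch, n_ch):
        raise DataError("adjacency shape must match the channel count")

    x = np.concatenate([xa, xb]).reshape(n1 + n2, -1)
    x2 = x**2
    s_tot = x.sum(axis=0)
    q_tot = x2.sum(axis=0)
    df = n1 + n2 - 2
    t_thresh = float(stats.t.ppf(1 - point_alpha / 2, df))

    graph = _spatiotemporal_graph(adjacency, n_t)

    ones = np.ones(n1 + n2, dtype=np.float64)
    sel0 = np.zeros(n1 + n2, dtype=np.float64)
    sel0[:n1] = 1.0
    t_obs_flat = _pooled_t(sel0 @ x, sel0 @ x2, s_tot, q_tot, n1, n2)
    obs_nodes, obs_masses = _cluster_masses(t_obs_flat, t_thresh, graph)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(_perm_chunk, n_perm - done)
        sel = np.zeros((k, n1 + n2), dtype=np.float64)
        for j in range(k):
            sel[j, rng.permutation(n1 + n2)[:n1]] = 1.0
        t_perm = _pooled_t(sel @ x, sel @ x2, s_tot, q_tot, n1, n2)
        for j in range(k):
            null_max[done + j] = _max_cluster_mass(t_perm[j], t_thresh, graph)
        done += k

    masks = []
    for members in obs_nodes:
        m = np.zeros(n_ch * n_t, dtype=bool)
        m[members] = True
        masks.append(m.reshape(n_ch, n_t))
    p_values = np.array(
        [
            (1.0 + np.sum(null_max >= abs(m))) / (n_perm + 1.0)
            for m in obs_masses
        ]
    )
    return ClusterTestResult(
        clusters=masks,
        cluster_stats=obs_masses,
        p_values=p_values,
        n_permutations=n_perm,
        point_alpha=point_alpha,
        cluster_alpha=cluster_alpha,
        t_obs=t_obs_flat.reshape(n_ch, n_t),
        t_threshold=t_thresh,
        null_max=null_max,
    )


# ---------------------------------------------------------------------------
# MRCP


@dataclass
class MRCPResult:
    """Trial-averaged low-frequency movement-related potential."""

    waveforms: np.ndarray        # (n_channels, n_times), 1-4 Hz band
    times: np.ndarray            # seconds relative to movement onset
    channel: int | None          # channel carrying the deepest negativity
    onset_time: float | None     # first sustained negativity, None if absent
    peak_time: float | None
    peak_amp: float | None

    @property
    def onset_lead(self) -> float | None:
        """Lead of the negativity onset before movement onset, in s."""
        return None if self.onset_time is None else -self.onset_time


def mrcp(
    epochs,
    band: tuple[float, float] = (1.0, 4.0),
    onset_k: float = 2.0,
    onset_min_duration: float = 0.05,
    baseline_duration: float = 0.15,
    filter_order: int = 1,
    smooth_window: float = 0.12,
    edge_margin: float = 0.05,
    slope_fraction: float = 0.05,
) -> MRCPResult:
    """Average trials, bandpass 1-4 Hz, find the negativity onset.

    Averaging and filtering commute, so the (zero-phase Butterworth,
    deliberately low order to limit distortion of the slow ramp)
    filter runs on the trial-averaged waveform.  The channel and the
    negative peak are selected inside the post-baseline interior of
    the epoch (the first ``baseline_duration`` seconds and the final
    ``edge_margin`` seconds are excluded; zero-phase filter edge
    transients live there).  The onset is where the sustained descent
    into the peak begins: from the point of steepest descent, walk
    back while the Savitzky-Golay-smoothed downward slope stays above
    ``slope_fraction`` of its maximum.  An onset is only reported when
    the peak is significant (below ``-onset_k`` baseline standard
    deviations) and the descent lasts at least ``onset_min_duration``;
    a value threshold alone cannot mark the onset because the 1 Hz
    high-pass gives the filtered ramp a positive lobe before the
    negativity.
    """
    trials = _as_trials(epochs)
    fs = float(getattr(epochs, "sampling_rate", 250.0))
    window = getattr(epochs, "window", None)
    t0 = window[0] if window is not None else -trials.shape[2] / fs
    if t0 >= 0:
        raise DataError("epochs must include pre-movement samples")
    times = t0 + np.arange(trials.shape[2]) / fs

    avg = trials.mean(axis=0)
    sos = signal.butter(filter_order, band, btype="bandpass", fs=fs, output="sos")
    wave = signal.sosfiltfilt(sos, avg, axis=1)

    n_base = max(2, int(round(baseline_duration * fs)))
    n_edge = max(1, int(round(edge_margin * fs)))
    interior = slice(n_base, max(n_base + 1, wave.shape[1] - n_edge))
    ch = int(np.argmin(wave[:, interior].min(axis=1)))
    w = wave[ch]
    base_sd = float(np.std(w[:n_base]))
    peak_idx = n_base + int(np.argmin(w[interior]))
    if base_sd == 0 or w[peak_idx] >= -onset_k * base_sd:
        return MRCPResult(wave, times, None, None, None, None)

    sg_win = max(5, int(round(smooth_window * fs)) | 1)
    down = -signal.savgol_filter(w, sg_win, 2, deriv=1, delta=1.0 / fs)
    seg = down[n_base : peak_idx + 1]
    if seg.size == 0 or seg.max() <= 0:
        return MRCPResult(wave, times, None, None, None, None)
    onset_idx = n_base + int(np.argmax(seg))
    while onset_idx > n_base and down[onset_idx - 1] > slope_fraction * seg.max():
        onset_idx -= 1
    if (peak_idx - onset_idx) / fs < onset_min_duration:
        return MRCPResult(wave, times, None, None, None, None)
    return MRCPResult(
        waveforms=wave,
        times=times,
        channel=ch,
        onset_time=float(times[onset_idx]),
        peak_time=float(times[peak_idx]),
        peak_amp=float(w[peak_idx]),
    )


# ---------------------------------------------------------------------------
# linear baseline


def baseline_logistic(
    datasets: dict[str, "object"],
    protocol: str = "loso",
    C: float = 1.0,
    max_iter: int = 2000,
    seed: int = 0,
) -> dict:
    """Leave-one-subject-out accuracy of a flattened-epoch linear model.

    ``datasets`` maps subject id -> `LabelledEpochSet` (same task).
    Each trial is flattened to a channels*time vector and classified
    with L2-regularized multinomial logistic regression.
    """
    from sklearn.linear_model import LogisticRegression

    if protocol != "loso":
        raise ValueError(f"unknown protocol {protocol!r}")
    subjects = list(datasets)
    if len(subjects) < 2:
        raise DataError("leave-one-subject-out needs at least 2 subjects")

    accuracies = {}
    for held_out in subjects:
        train_ids = [s for s in subjects if s != held_out]
        xtr = np.concatenate(
            [np.asarray(datasets[s].trials).reshape(len(datasets[s].trials), -1)
             for s in train_ids]
        )
        ytr = np.concatenate([datasets[s].labels for s in train_ids])
        if np.unique(ytr).size < 2:
            raise DataError("training fold contains a single class")
        clf = LogisticRegression(C=C, max_iter=max_iter, random_state=seed)
        clf.fit(xtr, ytr)
        ds = datasets[held_out]
        xte = np.asarray(ds.trials).reshape(len(ds.trials), -1)
        accuracies[held_out] = float(np.mean(clf.predict(xte) == ds.labels))

    values = np.array(list(accuracies.values()))
    return {
        "accuracies": accuracies,
        "mean": float(values.mean()),
        "sd": float(values.std()),
    }
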