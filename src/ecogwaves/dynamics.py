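"""Time-resolved band power and cluster-based permutation contrasts.

The time-frequency transform uses 1000 ms Hanning windows sliding in 50 ms
steps (1 Hz x 20 Hz resolution), after which session offsets are regressed
out, power is expressed as percent change from a bootstrapped pre-stimulus
baseline, and condition contrasts are evaluated with one-dimensional
cluster-based sign-flip permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats


@dataclass
class TimeFrequencyMap:
    times: np.ndarray  # s, window centers (0.05 s step)
    freqs: np.ndarray  # Hz (1 Hz step)
    power: np.ndarray  # (n_trials, n_channels, n_freqs, n_times)

    def band_series(self, band) -> np.ndarray:
        """Mean power over a frequency band -> (n_trials, n_channels, n_times)."""
        mask = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not mask.any():
            raise ValueError("band contains no frequency bins")
        return self.power[:, :, mask, :].mean(axis=2)


@dataclass
class Cluster:
    start: float  # s
    stop: float  # s
    mass: float  # summed t values
    p_value: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    t_values: np.ndarray | None = None
    threshold: float = np.nan

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def compute_tfr(
    trials: np.ndarray,
    sample_rate: float,
    window: float = 1.0,
    step: float = 0.05,
    fmax: float = 200.0,
    times_offset: float = 0.0,
) -> TimeFrequencyMap:
    """Sliding-window Hanning spectrogram per trial and channel.

    ``trials``: (n_trials, n_channels, n_samples).  ``times_offset`` places
    the time axis relative to the event of interest (e.g. -1.0 when epochs
    start 1 s before stimulus onset); times mark window centers.
    """
    x = np.asarray(trials, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    n_trials, n_ch, n_samp = x.shape
    nperseg = int(round(window * sample_rate))
    if n_samp < nperseg:
        raise ValueError("epoch shorter than one analysis window")
    taper = signal.get_window("hann", nperseg)
    # window starts snapped per-step so the nominal grid stays exactly at
    # ``step`` seconds even when step*sample_rate is not an integer
    n_wins = int(np.floor((n_samp - nperseg) / (step * sample_rate))) + 1
    starts = np.round(np.arange(n_wins) * step * sample_rate).astype(int)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / sample_rate)
    keep = (freqs > 0) & (freqs <= fmax)
    # windowed FFT; normalization matches a Welch density estimate
    scale = 1.0 / (sample_rate * (taper**2).sum())
    idx = starts[:, None] + np.arange(nperseg)[None, :]
    segs = x[:, :, idx] * taper  # (trials, ch, wins, nperseg)
    spec = np.fft.rfft(segs, axis=-1)
    power = (np.abs(spec) ** 2) * scale
    power[..., 1:-1] *= 2.0
    power = np.transpose(power[..., keep], (0, 1, 3, 2))
    times = times_offset + window / 2.0 + np.arange(n_wins) * step
    return TimeFrequencyMap(times=times, freqs=freqs[keep], power=power)


def correct_session_offsets(tfr: TimeFrequencyMap, sessions) -> TimeFrequencyMap:
    """Remove per-session offsets in absolute power.

    Fits a per-channel gain to each session's mean power (over all
    time-frequency estimates) and rescales so all sessions share the
    grand-mean level.  Multiplicative correction keeps power non-negative
    and leaves within-session relative structure untouched.
    """
    sessions = np.asarray(sessions)
    if sessions.shape[0] != tfr.power.shape[0]:
        raise ValueError("one session label per trial required")
    power = tfr.power.copy()
    grand = power.mean(axis=(0, 2, 3), keepdims=True)  # per channel
    for s in np.unique(sessions):
        m = sessions == s
        sess_mean = power[m].mean(axis=(0, 2, 3), keepdims=True)
        power[m] *= grand / sess_mean
    return TimeFrequencyMap(times=tfr.times, freqs=tfr.freqs, power=power)


def baseline_normalize(
    tfr: TimeFrequencyMap,
    window=(-0.75, -0.50),
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TimeFrequencyMap:
    """Percent change from bootstrapped baseline power.

    Baseline B is, per channel and frequency, the average over ``n_boot``
    bootstrap resamples (trials drawn with replacement) of the trial-mean
    power in the pre-stimulus window; output is 100*(power - B)/B.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tmask = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if not tmask.any():
        raise ValueError("baseline window outside epoch time range")
    base = tfr.power[:, :, :, tmask].mean(axis=3)  # (trials, ch, freq)
    n_trials = base.shape[0]
    draws = rng.integers(0, n_trials, size=(n_boot, n_trials))
    boot = base[draws].mean(axis=1)  # (n_boot, ch, freq)
    b = boot.mean(axis=0)
    if np.any(b <= 0):
        raise ValueError("zero or negative baseline power")
    pct = 100.0 * (tfr.power - b[None, :, :, None]) / b[None, :, :, None]
    return TimeFrequencyMap(times=tfr.times, freqs=tfr.freqs, power=pct)


def resample_to_common_duration(
    series: np.ndarray,
    current_duration: float,
    target_duration: float = 2.0,
    axis: int = -1,
) -> np.ndarray:
    """Map a time course to the sample count of a ``target_duration`` epoch.

    Resampling uses polyphase filtering (anti-aliasing built in), with
    linear-edge padding so ramps keep their endpoint values.
    """
    x = np.asarray(series, dtype=float)
    n_in = x.shape[axis]
    if current_duration <= 0:
        raise ValueError("current_duration must be positive")
    n_out = int(round(n_in * target_duration / current_duration))
    if n_out == n_in:
        return x.copy()
    return signal.resample_poly(x, n_out, n_in, axis=axis, padtype="line")


def _cluster_masses(t_vals: np.ndarray, threshold: float):
    """Contiguous supra-threshold runs of same-signed t values."""
    above = np.abs(t_vals) > threshold
    clusters = []
    i = 0
    n = len(t_vals)
    while i < n:
        if above[i]:
            sign = np.sign(t_vals[i])
            j = i
            while j < n and above[j] and np.sign(t_vals[j]) == sign:
                j += 1
            clusters.append((i, j, float(t_vals[i:j].sum())))
            i = j
        else:
            i += 1
    return clusters


def _paired_t(diff: np.ndarray):
    """t statistic of column means against zero; diff is (n_units, n_times)."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.finfo(float).eps, sd)
    return m / (sd / np.sqrt(n))


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray | None = None,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Dependent-samples cluster permutation test over time.

    ``cond_a``/``cond_b``: (n_units, n_times) paired observations.  Clusters
    form where the paired two-sided t exceeds its p<``alpha`` critical value;
    cluster mass is the summed t, and the permutation null flips the sign of
    each unit's difference (10,000 randomizations by default).  P-values use
    the (1 + exceedances)/(1 + n_perm) estimator.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shape")
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need >= 2 paired units")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_units, n_times = a.shape
    if times is None:
        times = np.arange(n_times, dtype=float)

    diff = a - b
    threshold = float(stats.t.ppf(1.0 - alpha / 2.0, df=n_units - 1))
    t_obs = _paired_t(diff)
    obs_clusters = _cluster_masses(t_obs, threshold)

    flips = rng.integers(0, 2, size=(n_perm, n_units)) * 2 - 1
    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        t_k = _paired_t(flips[k][:, None] * diff)
        cl = _cluster_masses(t_k, threshold)
        null_max[k] = max((abs(m) for _, _, m in cl), default=0.0)

    clusters = []
    for i, j, mass in obs_clusters:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(
            Cluster(start=float(times[i]), stop=float(times[j - 1]), mass=mass,
                    p_value=float(p), sign=int(np.sign(mass)))
        )
    return ClusterResult(clusters=clusters, t_values=t_obs, threshold=threshold)
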