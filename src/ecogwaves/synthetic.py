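"""Synthetic multichannel ECoG generator with known ground truth.

Produces recordings whose statistical structure matches what the analysis
pipeline assumes: 1/f^chi arrhythmic background, band-limited rhythms with
configurable center frequency and bandwidth, planar traveling-wave phase
lags, condition-dependent amplitude modulation, broadband 60-120 Hz
co-modulation, a trial structure with pre-stimulus baseline, and sine-law
grasp-choice behavior.  Every stochastic element is routed through a single
seeded generator recorded in the :class:`GroundTruth` object so downstream
recovery tests are closed-loop.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf

VALID_REGIONS = ("precentral", "postcentral", "other")
VALID_RESPONSES = ("motor", "somatosensory", "both", "none")
CONDITIONS = ("left", "right")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GridGeometry:
    """Planar electrode array layout with clinical annotations."""

    labels: list[str]
    positions: np.ndarray  # (n, 3) mm
    spacing: float  # mm
    region: list[str]
    stim_response: list[str]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        for r in self.region:
            if r not in VALID_REGIONS:
                raise ValueError(f"unknown region {r!r}")
        for s in self.stim_response:
            if s not in VALID_RESPONSES:
                raise ValueError(f"unknown stim_response {s!r}")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    @classmethod
    def regular_grid(cls, n_rows: int = 8, n_cols: int = 8, spacing: float = 10.0,
                     sulcus_col: float | None = None) -> "GridGeometry":
        """Build an n_rows x n_cols planar grid.

        Columns anterior of ``sulcus_col`` (default: array midline) are
        labeled precentral/motor, the rest postcentral/somatosensory.
        """
        if sulcus_col is None:
            sulcus_col = (n_cols - 1) / 2.0
        labels, pos, region, resp = [], [], [], []
        for i in range(n_rows):
            for j in range(n_cols):
                labels.append(f"G{i * n_cols + j + 1:02d}")
                pos.append((j * spacing, i * spacing, 0.0))
                if j < sulcus_col:
                    region.append("precentral")
                    resp.append("motor")
                else:
                    region.append("postcentral")
                    resp.append("somatosensory")
        return cls(labels, np.array(pos), spacing, region, resp)

    @classmethod
    def strip(cls, n: int, spacing: float = 10.0) -> "GridGeometry":
        labels = [f"S{i + 1:02d}" for i in range(n)]
        pos = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
        return cls(labels, pos, spacing, ["other"] * n, ["none"] * n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.labels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "region": self.region,
                "stim_response": self.stim_response,
            }
        )


@dataclass
class OscillationSpec:
    """One band-limited traveling rhythm."""

    center_freq: float  # Hz
    fwhm: float  # Hz, spectral full-width at half-maximum
    direction: float = 0.0  # degrees, propagation azimuth in the array plane
    speed: float = math.inf  # cm/s; inf = spatially synchronous
    amplitude_by_condition: dict = field(default_factory=lambda: {"left": 1.0, "right": 1.0})
    baseline_amplitude: float = 1.0
    spatial_gain: np.ndarray | None = None  # per-electrode amplitude, default uniform
    label: str = ""

    def __post_init__(self):
        if self.center_freq <= 0:
            raise ValueError("center_freq must be > 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if not self.speed > 0:
            raise ValueError("speed must be > 0 (use inf for synchronous)")


@dataclass
class TrialSpec:
    """Trial/session layout of the imagery task."""

    n_trials_per_session: int = 60
    n_sessions: int = 2
    trial_duration: float = 3.0  # s, cylinder on screen
    baseline_duration: float = 1.0  # s, pre-cylinder
    block_size: int = 10  # hand alternates every block
    n_orientations: int = 15

    @property
    def orientations(self) -> np.ndarray:
        """15 cylinder orientations, 24 degrees apart, spanning 0-360."""
        return np.arange(self.n_orientations) * (360.0 / self.n_orientations)

    @property
    def epoch_duration(self) -> float:
        return self.baseline_duration + self.trial_duration

    def hands(self) -> list[str]:
        out = []
        for t in range(self.n_trials_per_session):
            out.append(CONDITIONS[(t // self.block_size) % 2])
        return out


@dataclass
class BehaviorParams:
    """Sine-law grasp preference p(overhand) = a*sin(theta + phi0) + c."""

    amplitude: float = 0.45
    phase_deg: float = 0.0
    offset: float = 0.5


@dataclass
class GroundTruth:
    """Full parameterization of one synthetic dataset (round-trippable)."""

    fractal_exponent: float = 1.5
    oscillations: list[OscillationSpec] = field(default_factory=list)
    hfa_modulation: float = 0.3  # task-related broadband gain change (amplitude)
    noise_level: float = 1.0  # fractal background amplitude
    # trial-to-trial multiplicative jitter of the background level (shared
    # across frequencies): the confound that inflates raw band-power
    # correlations and that fractal/oscillatory separation removes
    background_trial_jitter: float = 0.25
    # independent per-trial amplitude jitter of each oscillation (envelope
    # variability uncorrelated between rhythms)
    oscillation_trial_jitter: float = 0.3
    seed: int = 0
    sample_rate: float = 512.0
    behavior: dict = field(
        default_factory=lambda: {
            "left": BehaviorParams(phase_deg=30.0),
            "right": BehaviorParams(phase_deg=-30.0),
        }
    )
    session_gains: list[float] | None = None  # per-session global amplitude offsets

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, OscillationSpec):
                d = dataclasses.asdict(obj)
                if d["spatial_gain"] is not None:
                    d["spatial_gain"] = np.asarray(d["spatial_gain"]).tolist()
                return d
            if isinstance(obj, BehaviorParams):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        d = dataclasses.asdict(self)
        d["oscillations"] = [json.loads(json.dumps(o, default=enc)) for o in self.oscillations]
        d["behavior"] = {k: dataclasses.asdict(v) if isinstance(v, BehaviorParams) else v
                         for k, v in self.behavior.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["oscillations"] = [
            OscillationSpec(
                **{**o, "spatial_gain": None if o.get("spatial_gain") is None
                   else np.asarray(o["spatial_gain"])}
            )
            for o in d["oscillations"]
        ]
        d["behavior"] = {k: BehaviorParams(**v) for k, v in d["behavior"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# signal forward models
# ---------------------------------------------------------------------------


def generate_fractal_background(
    n_channels: int,
    n_samples: int,
    sample_rate: float,
    exponent: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Channels of 1/f^exponent noise, unit variance, mutually independent.

    Synthesis is by spectral shaping: white Gaussian noise is transformed to
    the frequency domain and its amplitudes scaled by f^(-exponent/2), which
    yields the target power law exactly in expectation.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    out /= out.std(axis=-1, keepdims=True)
    return out


def narrowband_analytic(
    n_samples: int,
    sample_rate: float,
    center_freq: float,
    fwhm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Complex analytic narrowband carrier with a Gaussian PSD bump.

    Constructed directly in the frequency domain: complex Gaussian spectrum
    weighted by the square root of a Gaussian power profile centered on
    ``center_freq`` with spectral FWHM ``fwhm``, negative frequencies zeroed.
    The real part has unit RMS.
    """
    freqs = np.fft.fftfreq(n_samples, d=1.0 / sample_rate)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    amp = np.exp(-((freqs - center_freq) ** 2) / (4.0 * sigma**2))
    amp[freqs <= 0] = 0.0
    z = (rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples)) * amp
    analytic = np.fft.ifft(z)
    rms = np.sqrt(np.mean(analytic.real**2))
    return analytic / rms


def in_plane_coordinates(geometry: GridGeometry) -> np.ndarray:
    """Project electrode positions onto their first two principal axes (cm)."""
    pos = geometry.positions - geometry.positions.mean(axis=0)
    _, _, vt = np.linalg.svd(pos, full_matrices=False)
    return (pos @ vt[:2].T) / 10.0  # mm -> cm


def phase_lag_field(geometry: GridGeometry, spec: OscillationSpec) -> np.ndarray:
    """Exact per-electrode phase offset (rad) of the imposed plane wave.

    offset_i = -(2*pi*f / v) * (p_i . u), with p_i the in-plane position in
    cm and u the unit propagation vector.  Sites further along the travel
    direction lag (more negative phase).
    """
    if not math.isfinite(spec.speed):
        return np.zeros(geometry.n_electrodes)
    coords = in_plane_coordinates(geometry)
    theta = math.radians(spec.direction)
    u = np.array([math.cos(theta), math.sin(theta)])
    k = 2.0 * math.pi * spec.center_freq / spec.speed  # rad/cm
    return -k * (coords @ u)


def generate_traveling_oscillation(
    geometry: GridGeometry,
    spec: OscillationSpec,
    n_samples: int,
    sample_rate: float,
    seed: int | np.random.Generator = 0,
    envelope: np.ndarray | None = None,
) -> np.ndarray:
    """Band-limited oscillation traveling across the array as a plane wave.

    All channels share one narrowband carrier; the traveling structure is a
    constant per-channel phase rotation of its analytic representation, so
    the imposed phase-lag field is exactly planar before noise.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    carrier = narrowband_analytic(n_samples, sample_rate, spec.center_freq, spec.fwhm, rng)
    offsets = phase_lag_field(geometry, spec)
    out = np.real(np.exp(1j * offsets)[:, None] * carrier[None, :])
    if spec.spatial_gain is not None:
        out *= np.asarray(spec.spatial_gain, dtype=float)[:, None]
    if envelope is not None:
        out *= np.asarray(envelope, dtype=float)[None, :]
    return out


def _smooth_gate(n_samples, sample_rate, start, stop, low, high, ramp=0.1):
    """Envelope equal to ``low`` outside [start, stop] s and ``high`` inside,
    with raised-cosine ramps of ``ramp`` s."""
    t = np.arange(n_samples) / sample_rate
    gate = np.zeros(n_samples)
    for edge, sign in ((start, 1.0), (stop, -1.0)):
        x = np.clip((t - edge) / ramp + 0.5, 0.0, 1.0)
        gate += sign * 0.5 * (1 - np.cos(np.pi * x))
    gate -= gate.min()
    if gate.max() > 0:
        gate /= gate.max()
    return low + (high - low) * gate


def generate_hfa_burst_carrier(n_samples, sample_rate, rng, band=(60.0, 120.0)):
    """Broadband carrier restricted to ``band``, unit RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    return x / x.std()


# ---------------------------------------------------------------------------
# behavior forward model
# ---------------------------------------------------------------------------


def overhand_probability(orientations_deg, params: BehaviorParams) -> np.ndarray:
    theta = np.radians(np.asarray(orientations_deg, dtype=float))
    phi0 = math.radians(params.phase_deg)
    return np.clip(params.amplitude * np.sin(theta + phi0) + params.offset, 0.0, 1.0)


def generate_grasp_responses(
    orientations_deg,
    params: BehaviorParams,
    n_per_orientation: int,
    seed: int | np.random.Generator = 0,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Bernoulli grasp choices per presented orientation.

    In ``noiseless`` mode probabilities are rounded to {0, 1} first, giving
    a deterministic over/underhand pattern with two 50% crossings per cycle.
    """
    if n_per_orientation <= 0:
        raise ValueError("n_per_orientation must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for theta in np.asarray(orientations_deg, dtype=float):
        p = float(overhand_probability([theta], params)[0])
        if noiseless:
            p = round(p)
        draws = rng.random(n_per_orientation) < p
        for d in draws:
            rows.append({"orientation": theta, "choice": "overhand" if d else "underhand"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def default_ground_truth(geometry: GridGeometry, seed: int = 0) -> GroundTruth:
    """Defaults mirroring the qualitative condition pattern the pipeline
    should recover: ipsilateral (left-hand) alpha increase, contralateral
    (right-hand) beta decrease, on a left-hemisphere array."""
    n = geometry.n_electrodes
    coords = np.asarray(geometry.positions)
    # alpha sources in postcentral electrodes, beta straddling the midline
    post = np.array([r == "postcentral" for r in geometry.region])
    x = coords[:, 0]
    mid = 0.5 * (x.min() + x.max())
    alpha_gain = np.where(post, 1.0, 0.3)
    beta_gain = 0.3 + 0.7 * np.exp(-((x - mid) ** 2) / (2 * (1.5 * geometry.spacing) ** 2))
    # speeds chosen so the imposed wavenumber (2*pi*f/v ~ 1.4 rad/cm) stays
    # resolvable by 10-mm electrode spacing and 1-cm central differences
    alpha = OscillationSpec(
        center_freq=8.0, fwhm=4.0, direction=180.0, speed=35.0,
        amplitude_by_condition={"left": 1.3, "right": 1.0},
        spatial_gain=alpha_gain, label="alpha",
    )
    beta = OscillationSpec(
        center_freq=18.0, fwhm=6.0, direction=0.0, speed=80.0,
        amplitude_by_condition={"left": 1.0, "right": 0.8},
        spatial_gain=beta_gain, label="beta",
    )
    del n
    return GroundTruth(fractal_exponent=1.5, oscillations=[alpha, beta],
                       hfa_modulation=0.3, noise_level=1.0, seed=seed,
                       session_gains=None)


def assemble_dataset(
    geometry: GridGeometry,
    trial_spec: TrialSpec,
    ground_truth: GroundTruth,
    out_dir,
) -> dict:
    """Simulate a full recording and write EDF + TSV + JSON artifacts.

    Returns a dict of output paths: ``signals`` (EDF), ``electrodes``,
    ``events``, ``behavior`` (TSV) and ``ground_truth`` (JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = ground_truth.sample_rate
    if fs <= 0:
        raise ValueError("sample_rate must be positive")
    epoch_dur = trial_spec.epoch_duration
    n_epoch = int(round(epoch_dur * fs))
    if abs(n_epoch - epoch_dur * fs) > 1e-9:
        raise ValueError("epoch duration must be a whole number of samples")
    n_trials = trial_spec.n_trials_per_session
    n_sess = trial_spec.n_sessions
    n_sess_samples = n_epoch * n_trials
    rng = np.random.default_rng(ground_truth.seed)

    session_gains = ground_truth.session_gains
    if session_gains is None:
        session_gains = [1.0 + 0.2 * s for s in range(n_sess)]
    if len(session_gains) != n_sess:
        raise ValueError("session_gains length must equal n_sessions")

    orientations = trial_spec.orientations
    hands = trial_spec.hands()
    events_rows = []
    behavior_rows = []
    signal_parts = []
    t0 = 0.0
    for s in range(n_sess):
        # per-session orientation schedule: balanced pseudo-random
        n_rep = int(np.ceil(n_trials / len(orientations)))
        sched = np.tile(orientations, n_rep)[:n_trials]
        rng.shuffle(sched)

        sess = ground_truth.noise_level * generate_fractal_background(
            geometry.n_electrodes, n_sess_samples, fs, ground_truth.fractal_exponent, rng
        )
        if ground_truth.background_trial_jitter > 0:
            gains = 1.0 + ground_truth.background_trial_jitter * (
                2.0 * rng.random(n_trials) - 1.0
            )
            sess *= np.repeat(gains, n_epoch)[None, :]
        for spec in ground_truth.oscillations:
            env = np.ones(n_sess_samples)
            osc_jit = ground_truth.oscillation_trial_jitter
            trial_gains = 1.0 + osc_jit * (2.0 * rng.random(n_trials) - 1.0)
            for t, hand in enumerate(hands):
                amp = spec.amplitude_by_condition.get(hand, 1.0)
                seg = _smooth_gate(
                    n_epoch, fs,
                    trial_spec.baseline_duration,
                    trial_spec.baseline_duration + trial_spec.trial_duration,
                    spec.baseline_amplitude, amp,
                )
                env[t * n_epoch : (t + 1) * n_epoch] = seg * trial_gains[t]
            sess += generate_traveling_oscillation(
                geometry, spec, n_sess_samples, fs, rng, envelope=env
            )
        # broadband 60-120 Hz co-modulation, independent carrier per channel
        hfa_env = np.ones(n_sess_samples)
        for t, hand in enumerate(hands):
            seg = _smooth_gate(
                n_epoch, fs,
                trial_spec.baseline_duration,
                trial_spec.baseline_duration + trial_spec.trial_duration,
                1.0, 1.0 + ground_truth.hfa_modulation,
            )
            hfa_env[t * n_epoch : (t + 1) * n_epoch] = seg
        for ch in range(geometry.n_electrodes):
            sess[ch] += 0.5 * generate_hfa_burst_carrier(n_sess_samples, fs, rng) * hfa_env

        sess *= session_gains[s]
        signal_parts.append(sess)

        for t, hand in enumerate(hands):
            onset = t0 + t * epoch_dur + trial_spec.baseline_duration
            theta = float(sched[t])
            events_rows.append(
                {
                    "onset": onset,
                    "duration": trial_spec.trial_duration,
                    "hand": hand,
                    "orientation": theta,
                    "session": s + 1,
                }
            )
            p = float(overhand_probability([theta], ground_truth.behavior[hand])[0])
            behavior_rows.append(
                {
                    "orientation": theta,
                    "hand": hand,
                    "choice": "overhand" if rng.random() < p else "underhand",
                }
            )
        t0 += n_trials * epoch_dur

    signals = np.concatenate(signal_parts, axis=1)

    paths = {
        "signals": out_dir / "recording.edf",
        "electrodes": out_dir / "electrodes.tsv",
        "events": out_dir / "events.tsv",
        "behavior": out_dir / "behavior.tsv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_edf(paths["signals"], signals, fs, geometry.labels)
    geometry.to_frame().to_csv(paths["electrodes"], sep="\t", index=False)
    pd.DataFrame(events_rows).to_csv(paths["events"], sep="\t", index=False)
    pd.DataFrame(behavior_rows).to_csv(paths["behavior"], sep="\t", index=False)
    paths["ground_truth"].write_text(ground_truth.to_json())
    return {k: str(v) for k, v in paths.items()}
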