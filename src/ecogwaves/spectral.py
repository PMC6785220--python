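"""Rhythmic vs. arrhythmic spectral decomposition.

Implements irregular-resampling auto-spectral analysis (IRASA): the signal
is compressed and stretched by a set of non-integer factors before spectral
estimation, which displaces rhythmic peaks while leaving the scale-free 1/f
component invariant; the median across factors isolates the fractal
component and the residual is the rhythmic (oscillatory) spectrum.  On top
of that sit the band parameterization (sum-of-Gaussians), the 30-50 Hz
log-log slope as an excitation/inhibition index, and broadband 60-120 Hz
power taken from the fractal component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import optimize, signal

# Non-integer resampling factors.  The range extends beyond the classic
# 1.1-1.9 set (integer 2.0 excluded) because individual rhythm bands several
# Hz wide leak into the fractal estimate when all factors keep the displaced
# peak nearby; larger factors move it clear of the band.
DEFAULT_IRASA_FACTORS = tuple(
    round(h, 2) for h in np.arange(1.1, 2.95, 0.05) if abs(h - 2.0) > 1e-9
)
# Combining statistic across factors: a sub-median quantile counteracts the
# upward contamination of factor spectra that still overlap a broad rhythm
# peak (contamination is strictly one-sided).
DEFAULT_IRASA_QUANTILE = 0.35
SLOPE_BAND = (30.0, 50.0)
HFA_BAND = (60.0, 120.0)


class NoRhythmError(ValueError):
    """Raised when no rhythmic component is present to parameterize."""


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing 1-D")
        if self.power.shape[-1] != self.freqs.shape[0]:
            raise ValueError("power/freqs shape mismatch")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power must be finite")

    def band_mask(self, band) -> np.ndarray:
        return (self.freqs >= band[0]) & (self.freqs <= band[1])


@dataclass
class FractalFit:
    slope: float  # log10 power per log10 Hz
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class RhythmBand:
    center: float  # Hz
    fwhm: float  # Hz
    amplitude: float
    label: str = ""

    def __post_init__(self):
        if self.center <= 0 or self.fwhm <= 0:
            raise ValueError("center and fwhm must be positive")

    @property
    def band(self) -> tuple[float, float]:
        return (self.center - self.fwhm / 2.0, self.center + self.fwhm / 2.0)


@dataclass
class SpectralProfile:
    """Per-electrode decomposition products."""

    labels: list[str]
    freqs: np.ndarray
    original: np.ndarray  # (n_electrodes, n_freqs)
    fractal: np.ndarray
    oscillatory: np.ndarray  # clamped, >= 0
    bands: list[RhythmBand] = field(default_factory=list)
    slope_fits: list[FractalFit] = field(default_factory=list)
    hfa: np.ndarray | None = None  # (n_electrodes,)


def compute_psd(segment, sample_rate, fmax: float = 200.0, window: str = "hann") -> PowerSpectrum:
    """Hanning-tapered Welch spectrum with 1-second windows (1 Hz bins).

    Accepts 1-D ``(n_samples,)`` or 2-D ``(n_epochs, n_samples)`` input; epochs
    are averaged.  Frequencies above ``fmax`` are discarded.
    """
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    nperseg = int(round(sample_rate))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"segment length {x.shape[-1]} shorter than one {nperseg}-sample window"
        )
    freqs, pxx = signal.welch(
        x, fs=sample_rate, window=window, nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False, axis=-1,
    )
    pxx = pxx.mean(axis=0)
    keep = (freqs > 0) & (freqs <= fmax)
    return PowerSpectrum(freqs[keep], pxx[keep])


def _resample_by(x: np.ndarray, factor: float) -> np.ndarray:
    frac = Fraction(factor).limit_denominator(100)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def irasa(
    segment,
    sample_rate,
    factors=DEFAULT_IRASA_FACTORS,
    fmax: float = 200.0,
    quantile: float = DEFAULT_IRASA_QUANTILE,
) -> tuple[PowerSpectrum, PowerSpectrum]:
    """Separate a signal's spectrum into fractal and oscillatory parts.

    For each resampling factor h the signal is resampled by h and by 1/h;
    both auto-spectra (estimated as if still at the native rate, so the
    frequency axis is scaled by h and 1/h respectively) are combined by
    geometric mean, which cancels the power-law rescaling exactly while
    moving any rhythmic peak to two different frequencies.  The ``quantile``
    across factors (0.5 = the classic median) is the fractal spectrum;
    oscillatory = original - fractal (additive, unclamped).
    """
    factors = [float(h) for h in factors]
    if len(factors) == 0:
        raise ValueError("factor set must not be empty")
    for h in factors:
        if h <= 1.0:
            raise ValueError("factors must all be > 1")
        if abs(h - round(h)) < 1e-9:
            raise ValueError("factors must be non-integer")

    x = np.atleast_2d(np.asarray(segment, dtype=float))
    original = compute_psd(x, sample_rate, fmax=fmax)
    geo_means = []
    for h in factors:
        up = _resample_by(x, h)
        down = _resample_by(x, 1.0 / h)
        psd_up = compute_psd(up, sample_rate, fmax=fmax)
        psd_dn = compute_psd(down, sample_rate, fmax=fmax)
        geo_means.append(np.sqrt(psd_up.power * psd_dn.power))
    fractal_power = np.quantile(geo_means, quantile, axis=0)
    fractal = PowerSpectrum(original.freqs, fractal_power)
    oscillatory = PowerSpectrum(original.freqs, original.power - fractal_power)
    return fractal, oscillatory


def clamp_negative(oscillatory: PowerSpectrum) -> PowerSpectrum:
    """Zero out negative oscillatory power (separation artifacts off-peak)."""
    return PowerSpectrum(oscillatory.freqs, np.maximum(oscillatory.power, 0.0))


def _gaussians(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        a, b, c = params[i : i + 3]
        out = out + a * np.exp(-(((f - b) / c) ** 2))
    return out


_FWHM_PER_C = 2.0 * math.sqrt(math.log(2.0))


def fit_rhythm_bands(
    oscillatory: PowerSpectrum,
    model_order: str | int = "auto",
    fit_range=(2.0, 45.0),
    low_freq_cutoff: float = 5.0,
) -> list[RhythmBand]:
    """Sum-of-Gaussians parameterization of the rhythmic spectrum.

    Fits a two-term model a*exp(-((f-b)/c)^2) by default; in ``auto`` mode a
    third term is added when a local maximum below ``low_freq_cutoff``
    exceeds 10% of the global oscillatory peak.  Returns bands sorted by
    center frequency and labeled low / alpha / beta.
    """
    if model_order not in ("auto", 2, 3):
        raise ValueError("model_order must be 'auto', 2 or 3")
    mask = oscillatory.band_mask(fit_range)
    f = oscillatory.freqs[mask]
    p = np.maximum(oscillatory.power[mask], 0.0)
    if p.size < 9 or np.all(p == 0):
        raise NoRhythmError("oscillatory spectrum carries no rhythmic power")

    peaks, props = signal.find_peaks(p, height=0.05 * p.max())
    order = np.argsort(props["peak_heights"])[::-1]
    peak_freqs = f[peaks[order]]
    peak_heights = props["peak_heights"][order]

    n_terms = model_order if isinstance(model_order, int) else 2
    if model_order == "auto":
        low = [(pf, ph) for pf, ph in zip(peak_freqs, peak_heights) if pf < low_freq_cutoff]
        if low and max(ph for _, ph in low) > 0.10 * p.max():
            n_terms = 3

    # initial guesses: strongest peaks, split low/high when 2 terms
    guesses = []
    if n_terms == 3:
        lows = [pf for pf in peak_freqs if pf < low_freq_cutoff]
        guesses.append(lows[0] if lows else 3.0)
    highs = [pf for pf in peak_freqs if pf >= low_freq_cutoff]
    if len(highs) >= 2:
        lo, hi = sorted(highs[:2])
        guesses += [lo, hi]
    elif len(highs) == 1:
        guesses += [highs[0], min(highs[0] * 2.0, 40.0)]
    else:
        guesses += [8.0, 18.0]

    p0, lower, upper = [], [], []
    for b0 in guesses:
        a0 = max(np.interp(b0, f, p), 1e-3 * p.max())
        p0 += [a0, b0, 2.0]
        lower += [0.0, fit_range[0], 0.3]
        upper += [np.inf, fit_range[1], 30.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, _ = optimize.curve_fit(
                _gaussians, f, p, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except RuntimeError as exc:
            raise NoRhythmError(f"band model did not converge: {exc}") from exc

    bands = []
    for i in range(0, len(popt), 3):
        a, b, c = popt[i : i + 3]
        if a <= 0:
            continue
        bands.append(RhythmBand(center=b, fwhm=_FWHM_PER_C * c, amplitude=a))
    bands.sort(key=lambda rb: rb.center)
    for rb in bands:
        rb.label = "low" if rb.center < low_freq_cutoff else ""
    named = [rb for rb in bands if rb.label != "low"]
    if len(named) >= 2:
        named[0].label, named[-1].label = "alpha", "beta"
    elif len(named) == 1:
        named[0].label = "beta" if named[0].center >= 13.0 else "alpha"
    return bands


def fit_fractal_slope(fractal: PowerSpectrum, band=SLOPE_BAND) -> FractalFit:
    """Straight-line fit of log10(power) on log10(frequency) over 30-50 Hz.

    A steeper (more negative) slope indexes greater net inhibition.
    """
    mask = fractal.band_mask(band)
    f = fractal.freqs[mask]
    p = fractal.power[mask] if fractal.power.ndim == 1 else fractal.power[..., mask]
    if f.size < 2:
        raise ValueError("band contains fewer than 2 frequency bins")
    if np.any(p <= 0):
        raise ValueError("fractal power must be positive across the fit band")
    lx, ly = np.log10(f), np.log10(p)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - np.sum(resid**2) / ss_tot)
    return FractalFit(slope=float(slope), intercept=float(intercept), r_squared=float(min(r2, 1.0)))


def hfa_power(fractal: PowerSpectrum, band=HFA_BAND) -> float:
    """Mean arrhythmic power over the broad 60-120 Hz range."""
    if band[0] < fractal.freqs[0] or band[1] > fractal.freqs[-1]:
        raise ValueError("band lies outside the spectrum's frequency range")
    mask = fractal.band_mask(band)
    return float(np.mean(fractal.power[mask]))


def band_power(spectrum: PowerSpectrum, band) -> float:
    """Mean power within a frequency band."""
    mask = spectrum.band_mask(band)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(np.mean(spectrum.power[mask]))


def decompose_electrodes(
    epochs: np.ndarray,
    sample_rate: float,
    labels: list[str],
    factors=DEFAULT_IRASA_FACTORS,
    model_order: str | int = "auto",
) -> SpectralProfile:
    """Run the full decomposition for every electrode.

    ``epochs``: (n_trials, n_electrodes, n_samples) task epochs, pooled per
    electrode for spectral estimation.  Band fitting uses the oscillatory
    spectrum averaged over electrodes (bands are a per-dataset property);
    slope and HFA are per electrode.
    """
    n_trials, n_el, _ = epochs.shape
    original = []
    fractal = []
    oscillatory = []
    freqs = None
    for e in range(n_el):
        frac, osc = irasa(epochs[:, e, :], sample_rate, factors=factors)
        freqs = frac.freqs
        fractal.append(frac.power)
        oscillatory.append(osc.power)
        original.append(frac.power + osc.power)
    original = np.array(original)
    fractal = np.array(fractal)
    osc_clamped = np.maximum(np.array(oscillatory), 0.0)

    mean_osc = PowerSpectrum(freqs, osc_clamped.mean(axis=0))
    bands = fit_rhythm_bands(mean_osc, model_order=model_order)
    slopes = [fit_fractal_slope(PowerSpectrum(freqs, fractal[e])) for e in range(n_el)]
    hfa = np.array([hfa_power(PowerSpectrum(freqs, fractal[e])) for e in range(n_el)])
    return SpectralProfile(
        labels=list(labels), freqs=freqs, original=original, fractal=fractal,
        oscillatory=osc_clamped, bands=bands, slope_fits=slopes, hfa=hfa,
    )
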