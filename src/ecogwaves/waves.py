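"""Traveling-wave quantification on electrode arrays.

Pipeline: zero-phase Butterworth band filtering -> analytic-signal phase ->
projection of electrode positions onto their two principal axes ->
interpolation of phases onto a regular 1 cm planar grid -> circular finite
differences (the spatial phase gradient) -> phase-gradient directionality
(PGD), propagation direction and speed, permutation nulls, directional
consistency, Rayleigh uniformity tests, KL divergence between direction
distributions, and relative phase maps.

Sign conventions: a positive phase shift means a site leads the oscillation;
the wave propagates along -grad(phi), from leading to lagging sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal, special


@dataclass
class GradientField:
    xs: np.ndarray  # grid x coordinates, cm
    ys: np.ndarray  # grid y coordinates, cm
    gx: np.ndarray  # d(phi)/dx, rad/cm, (ny, nx)
    gy: np.ndarray  # d(phi)/dy, rad/cm
    valid: np.ndarray  # bool (ny, nx)

    def vectors(self) -> np.ndarray:
        """Valid gradient vectors as an (n, 2) array."""
        return np.column_stack([self.gx[self.valid], self.gy[self.valid]])


@dataclass
class WaveMetrics:
    pgd: float
    direction: float  # degrees
    speed: float  # cm/s


@dataclass
class DirectionDistribution:
    bin_edges: np.ndarray  # radians
    probabilities: np.ndarray

    def __post_init__(self):
        if not math.isclose(float(np.sum(self.probabilities)), 1.0, rel_tol=1e-9):
            raise ValueError("probabilities must sum to 1")


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2.0 * np.pi)


def circular_mean(phi: np.ndarray, axis=None) -> np.ndarray:
    return np.angle(np.mean(np.exp(1j * np.asarray(phi)), axis=axis))


def resultant_length(phi: np.ndarray, axis=None) -> np.ndarray:
    return np.abs(np.mean(np.exp(1j * np.asarray(phi)), axis=axis))


# ---------------------------------------------------------------------------
# filtering and phase extraction
# ---------------------------------------------------------------------------


def bandpass(x: np.ndarray, sample_rate: float, center: float, fwhm: float) -> np.ndarray:
    """Two-pass (zero-phase) third-order Butterworth bandpass.

    Band edges are center +/- fwhm/2 and must lie inside (0, Nyquist).
    """
    lo, hi = center - fwhm / 2.0, center + fwhm / 2.0
    nyq = sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def instantaneous_phase(filtered: np.ndarray, pad_fraction: float = 0.25) -> np.ndarray:
    """Analytic-signal phase, with reflective edge padding.

    The Hilbert transform is evaluated on an edge-padded copy (reflected,
    ``pad_fraction`` of the signal length per side) and trimmed back, which
    suppresses the transform's boundary artifacts.
    """
    x = np.asarray(filtered, dtype=float)
    n = x.shape[-1]
    pad = max(1, int(pad_fraction * n))
    xp = np.concatenate(
        [x[..., 1 : pad + 1][..., ::-1], x, x[..., -pad - 1 : -1][..., ::-1]],
        axis=-1,
    )
    analytic = signal.hilbert(xp, axis=-1)[..., pad : pad + n]
    return np.angle(analytic)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def project_to_plane(positions_3d: np.ndarray) -> np.ndarray:
    """Orthonormal projection onto the array's first two principal axes (cm).

    Planar arrays keep pairwise distances exactly; input is in mm.
    """
    pos = np.asarray(positions_3d, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 3:
        raise ValueError("need >= 3 electrodes with 3-D positions")
    centered = pos - pos.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) electrode geometry")
    return (centered @ vt[:2].T) / 10.0


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


def _circ_diff(a, b):
    return np.angle(np.exp(1j * (a - b)))


# Delaunay triangulations are cached per electrode layout: permutation nulls
# evaluate thousands of snapshots on the same coordinates.
_TRI_CACHE: dict = {}


def _interpolate(coords, values, pts, method):
    if method != "linear":
        return interpolate.griddata(coords, values, pts, method=method)
    key = (coords.shape, coords.tobytes())
    tri = _TRI_CACHE.get(key)
    if tri is None:
        from scipy.spatial import Delaunay

        if len(_TRI_CACHE) > 16:
            _TRI_CACHE.clear()
        tri = _TRI_CACHE[key] = Delaunay(coords)
    return interpolate.LinearNDInterpolator(tri, values)(pts)


def phase_gradient(
    phases: np.ndarray,
    coords_2d: np.ndarray,
    step: float = 1.0,
    method: str = "linear",
) -> GradientField:
    """Spatial phase gradient on a regular planar grid.

    Phases at (possibly irregular) electrode sites are interpolated onto a
    ``step``-cm grid through their unit-vector representation (respecting
    circularity), then differentiated with wrapped central differences in
    both principal directions.  Sites without enough neighbors (outside the
    interpolation hull, or grid edges with one-sided data only) are masked.
    """
    phases = np.asarray(phases, dtype=float)
    coords = np.asarray(coords_2d, dtype=float)
    if phases.shape[0] != coords.shape[0]:
        raise ValueError("one phase per electrode required")
    xs = np.arange(coords[:, 0].min(), coords[:, 0].max() + step / 2, step)
    ys = np.arange(coords[:, 1].min(), coords[:, 1].max() + step / 2, step)
    gxgrid, gygrid = np.meshgrid(xs, ys)
    pts = np.column_stack([gxgrid.ravel(), gygrid.ravel()])

    cosv = _interpolate(coords, np.cos(phases), pts, method)
    sinv = _interpolate(coords, np.sin(phases), pts, method)
    phi = np.arctan2(sinv, cosv).reshape(len(ys), len(xs))
    known = np.isfinite(cosv.reshape(len(ys), len(xs)))

    ny, nx = phi.shape
    gx = np.full_like(phi, np.nan)
    gy = np.full_like(phi, np.nan)
    # wrapped central differences; one-sided at grid borders
    for (grad, axis, h) in ((gx, 1, step), (gy, 0, step)):
        fwd = np.roll(phi, -1, axis=axis)
        bwd = np.roll(phi, 1, axis=axis)
        ok_f = np.roll(known, -1, axis=axis) & known
        ok_b = np.roll(known, 1, axis=axis) & known
        if axis == 1:
            ok_f[:, -1] = False
            ok_b[:, 0] = False
        else:
            ok_f[-1, :] = False
            ok_b[0, :] = False
        central = ok_f & ok_b
        grad[central] = _circ_diff(fwd[central], bwd[central]) / (2 * h)
        only_f = ok_f & ~ok_b
        grad[only_f] = _circ_diff(fwd[only_f], phi[only_f]) / h
        only_b = ok_b & ~ok_f
        grad[only_b] = _circ_diff(phi[only_b], bwd[only_b]) / h
    valid = np.isfinite(gx) & np.isfinite(gy)
    return GradientField(xs=xs, ys=ys, gx=gx, gy=gy, valid=valid)


def pgd(gradient: GradientField) -> float:
    """Phase-gradient directionality: |mean gradient| / mean |gradient|.

    1 for a perfectly aligned planar wave, ~0 for incoherent gradients.
    """
    vec = gradient.vectors()
    if vec.shape[0] < 2:
        raise ValueError("need >= 2 valid gradient sites")
    norms = np.linalg.norm(vec, axis=1)
    denom = norms.mean()
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(vec.mean(axis=0)) / denom)


def wave_direction(gradient: GradientField) -> float:
    """Propagation azimuth in degrees: the direction of -mean(grad phi)."""
    vec = gradient.vectors()
    mean_g = vec.mean(axis=0)
    if np.linalg.norm(mean_g) < 1e-12:
        raise ValueError("undefined direction: zero mean gradient")
    ang = math.degrees(math.atan2(-mean_g[1], -mean_g[0]))
    return ang % 360.0


def wave_speed(mean_frequency: float, gradient: GradientField, reducer=np.median) -> float:
    """Propagation speed in cm/s: 2*pi*f divided by the gradient magnitude.

    Uses the median magnitude by default for robustness to near-zero sites.
    """
    vec = gradient.vectors()
    mags = np.linalg.norm(vec, axis=1)
    k = float(reducer(mags))
    if k <= 0:
        raise ValueError("undefined speed: zero gradient magnitude")
    return 2.0 * math.pi * mean_frequency / k


def wave_metrics(phases, coords_2d, mean_frequency, step=1.0) -> WaveMetrics:
    g = phase_gradient(phases, coords_2d, step=step)
    return WaveMetrics(pgd=pgd(g), direction=wave_direction(g),
                       speed=wave_speed(mean_frequency, g))


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------


def mean_pgd(phase_data: np.ndarray, coords_2d: np.ndarray,
             step: float = 1.0, time_indices=None) -> float:
    """Mean PGD across the sampled time points of (n_channels, n_times) phases."""
    if time_indices is None:
        time_indices = range(phase_data.shape[1])
    vals = [pgd(phase_gradient(phase_data[:, t], coords_2d, step=step))
            for t in time_indices]
    return float(np.mean(vals))


def pgd_null(
    phase_data: np.ndarray,
    coords_2d: np.ndarray,
    scheme: str = "electrode_shuffle",
    n_perm: int = 200,
    step: float = 1.0,
    n_time_samples: int = 20,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for the observed mean PGD.

    ``time_shuffle`` permutes time points independently per electrode
    (redistributing activity over time); ``electrode_shuffle`` permutes
    electrode locations within the array (redistributing activity over
    space).  Returns (observed, p, null distribution) with the plus-one
    estimator p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if scheme not in ("time_shuffle", "electrode_shuffle"):
        raise ValueError("scheme must be 'time_shuffle' or 'electrode_shuffle'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_ch, n_times = phase_data.shape
    t_idx = np.linspace(0, n_times - 1, min(n_time_samples, n_times)).astype(int)
    observed = mean_pgd(phase_data, coords_2d, step=step, time_indices=t_idx)

    null = np.zeros(n_perm)
    for k in range(n_perm):
        if scheme == "time_shuffle":
            shuffled = np.array([phase_data[c, rng.permutation(n_times)] for c in range(n_ch)])
            null[k] = mean_pgd(shuffled, coords_2d, step=step, time_indices=t_idx)
        else:
            perm = rng.permutation(n_ch)
            null[k] = mean_pgd(phase_data[perm], coords_2d, step=step, time_indices=t_idx)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return observed, float(p), null


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------


def directional_consistency(directions: np.ndarray) -> np.ndarray:
    """Mean resultant length across trials of per-trial directions.

    ``directions``: (n_trials, ...) angles in radians; the trial axis is
    reduced.  NaN entries are treated as missing (masked out per cell).
    """
    d = np.asarray(directions, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    z = np.exp(1j * d)
    z = np.where(np.isnan(d), np.nan + 0j, z)
    with np.errstate(invalid="ignore"):
        return np.abs(np.nanmean(z, axis=0))


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (z, p) with z = n*R^2 and the standard series approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R_n^2)) - (1 + 2n)).
    """
    a = np.asarray(angles, dtype=float).ravel()
    n = a.size
    if n < 5:
        raise ValueError("need n >= 5 angles")
    r = resultant_length(a)
    z = n * r**2
    rn = n * r
    p = math.exp(math.sqrt(max(1 + 4 * n + 4 * (n**2 - rn**2), 0.0)) - (1 + 2 * n))
    return float(z), float(min(p, 1.0))


def direction_histogram(angles: np.ndarray, n_bins: int = 36) -> DirectionDistribution:
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(wrap_phase(np.asarray(angles).ravel()), bins=edges)
    probs = counts / counts.sum()
    return DirectionDistribution(bin_edges=edges, probabilities=probs)


def _kl(p: np.ndarray, q: np.ndarray, eps: float) -> float:
    p = p + eps
    q = q + eps
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(special.rel_entr(p, q)))


def direction_kl(
    angles_a: np.ndarray,
    angles_b: np.ndarray,
    n_bins: int = 36,
    n_perm: int = 1000,
    eps: float = 1e-6,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """KL divergence between two direction distributions, with a shuffle p.

    Both angle samples are histogrammed on a common binning (empty bins
    regularized by ``eps``); the null pools the samples and re-splits them
    at random ``n_perm`` times.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = wrap_phase(np.asarray(angles_a, dtype=float).ravel())
    b = wrap_phase(np.asarray(angles_b, dtype=float).ravel())
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)

    def hist(x):
        c, _ = np.histogram(x, bins=edges)
        return c.astype(float) / max(c.sum(), 1)

    kl_obs = _kl(hist(a), hist(b), eps)
    pool = np.concatenate([a, b])
    na = a.size
    null = np.zeros(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pool.size)
        null[k] = _kl(hist(pool[perm[:na]]), hist(pool[perm[na:]]), eps)
    p = (1.0 + np.sum(null >= kl_obs)) / (1.0 + n_perm)
    return kl_obs, float(p)


def relative_phase_map(
    phase_data: np.ndarray,
    reference: int,
) -> np.ndarray:
    """Circular-mean phase of each electrode relative to a reference.

    ``phase_data``: (..., n_channels, n_times); trial and time axes are
    averaged on the unit circle.  The reference electrode maps to 0.
    """
    phi = np.asarray(phase_data, dtype=float)
    if phi.ndim == 2:
        phi = phi[None, ...]
    n_ch = phi.shape[1]
    if not (0 <= reference < n_ch):
        raise ValueError("reference electrode index out of range")
    rel = phi - phi[:, reference : reference + 1, :]
    return circular_mean(rel.transpose(1, 0, 2).reshape(n_ch, -1), axis=1)
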