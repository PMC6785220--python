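"""Psychophysics of grasp choices: sine fit, switch points, demand bins."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


class NoSwitchPointError(ValueError):
    """The fitted preference curve never crosses 50%."""


@dataclass
class PsychometricFit:
    """p(overhand) = amplitude * sin(theta + phase) + offset, theta in degrees."""

    amplitude: float
    phase_deg: float
    offset: float
    r_squared: float
    switch_points: list[float] = field(default_factory=list)

    def predict(self, orientations_deg) -> np.ndarray:
        theta = np.radians(np.asarray(orientations_deg, dtype=float))
        return self.amplitude * np.sin(theta + math.radians(self.phase_deg)) + self.offset


def fit_sine_psychometric(orientations_deg, p_overhand) -> PsychometricFit:
    """Least-squares sine fit (360-degree period) to choice proportions.

    The model a*sin(theta + phi0) + c is linear in (a*cos(phi0), a*sin(phi0),
    c), so the fit is an exact linear least-squares solution.  Amplitude is
    reported non-negative with phase in [0, 360).
    """
    theta = np.radians(np.asarray(orientations_deg, dtype=float))
    p = np.asarray(p_overhand, dtype=float)
    if len(np.unique(np.asarray(orientations_deg))) < 4:
        raise ValueError("need >= 4 distinct orientations")
    if np.allclose(p, p[0]):
        warnings.warn("constant choice data: zero-amplitude fit", stacklevel=2)
        return PsychometricFit(0.0, 0.0, float(p[0]), 0.0, [])
    design = np.column_stack([np.sin(theta), np.cos(theta), np.ones_like(theta)])
    (s_coef, c_coef, offset), *_ = np.linalg.lstsq(design, p, rcond=None)
    amplitude = math.hypot(s_coef, c_coef)
    phase = math.degrees(math.atan2(c_coef, s_coef)) % 360.0
    pred = design @ (s_coef, c_coef, offset)
    ss_res = float(np.sum((p - pred) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    fit = PsychometricFit(amplitude, phase, float(offset), max(0.0, min(1.0, r2)))
    try:
        fit.switch_points = find_switch_points(fit)
    except NoSwitchPointError:
        fit.switch_points = []
    return fit


def find_switch_points(fit: PsychometricFit) -> list[float]:
    """The two orientations where the fitted curve crosses 50%.

    Solves a*sin(theta + phi0) + c = 0.5; requires |0.5 - c| <= |a|.
    """
    if fit.amplitude == 0 or abs(0.5 - fit.offset) > abs(fit.amplitude):
        raise NoSwitchPointError("fitted curve does not cross 50%")
    s = (0.5 - fit.offset) / fit.amplitude
    base = math.degrees(math.asin(max(-1.0, min(1.0, s))))
    sols = [(base - fit.phase_deg) % 360.0, (180.0 - base - fit.phase_deg) % 360.0]
    return sorted(set(round(x, 10) % 360.0 for x in sols))


def _circ_dist_deg(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def label_demand(orientations_deg, switch_points, half_width: float = 24.0) -> np.ndarray:
    """Label trials as high / low / neither selection demand.

    High: within +/- ``half_width`` degrees of a switch point.  Low: within
    the equivalent range around switch point + 90 degrees (orthogonal
    orientations).  Everything else: neither.
    """
    theta = np.asarray(orientations_deg, dtype=float)
    sps = np.asarray(list(switch_points), dtype=float)
    if sps.size == 0:
        raise ValueError("no switch points provided")
    d_high = np.min([_circ_dist_deg(theta, sp) for sp in sps], axis=0)
    d_low = np.min([_circ_dist_deg(theta, (sp + 90.0) % 360.0) for sp in sps], axis=0)
    out = np.full(theta.shape, "neither", dtype=object)
    out[d_low <= half_width] = "low"
    out[d_high <= half_width] = "high"  # high wins at overlap (ties impossible at 24)
    return out
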