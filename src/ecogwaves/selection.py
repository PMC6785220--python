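"""Electrode localization: stimulation-positive restriction, confidence-bound
local maxima, and category/overlap/distance statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STIM_POSITIVE = ("motor", "somatosensory", "both")
Z_99 = float(stats.norm.ppf(0.995))  # two-sided 99% CI quantile


class NoCoverageError(ValueError):
    """No stimulation-positive electrodes: no sensorimotor coverage."""


@dataclass
class SelectionResult:
    feature: str  # 'alpha' | 'beta' | 'hfa' | 'slope' | ...
    selected: list[str]
    threshold: float
    tail: str  # 'upper' | 'lower'
    skipped: bool = False  # True when too few electrodes to narrow down


def select_stimulation_positive(electrode_table: pd.DataFrame) -> pd.DataFrame:
    """Electrodes whose stimulation evoked motor or somatosensory responses."""
    if "stim_response" not in electrode_table.columns:
        raise KeyError("electrode table lacks a 'stim_response' column")
    out = electrode_table[electrode_table["stim_response"].isin(STIM_POSITIVE)]
    if len(out) == 0:
        raise NoCoverageError("no stimulation-positive electrodes")
    return out.copy()


def find_local_maxima(
    values: pd.Series,
    tail: str = "upper",
    feature: str = "",
    z: float = Z_99,
) -> SelectionResult:
    """Electrodes beyond the 99% confidence bound of the across-electrode mean.

    Upper tail: value > mean + z*SEM.  Lower tail (used for the 1/f slope,
    where more negative means stronger inhibition): value < mean - z*SEM.
    With fewer than 3 electrodes the selection cannot be narrowed down; all
    electrodes are kept and the result is flagged ``skipped``.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    vals = values.astype(float)
    if len(vals) < 3:
        warnings.warn(
            "fewer than 3 electrodes: selection skipped, keeping all", stacklevel=2
        )
        return SelectionResult(feature, list(vals.index), np.nan, tail, skipped=True)
    sem = vals.std(ddof=1) / np.sqrt(len(vals))
    if tail == "upper":
        thr = vals.mean() + z * sem
        mask = vals > thr
    else:
        thr = vals.mean() - z * sem
        mask = vals < thr
    return SelectionResult(feature, list(vals.index[mask]), float(thr), tail)


def category_test(observed, expected_proportions=None):
    """Pearson goodness-of-fit chi-squared over category counts.

    Returns (chi2, df, p) with df = n_categories - 1.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if expected_proportions is None:
        exp = np.full(obs.size, obs.sum() / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        exp = props / props.sum() * obs.sum()
    if np.any(exp == 0):
        raise ValueError("expected count of zero")
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), obs.size - 1, float(p)


def overlap_and_separation(set_a, set_b, positions: pd.DataFrame):
    """Shared electrode count and mean nearest-neighbor distance (mm).

    Distance is the mean over electrodes in A of the distance to the nearest
    electrode in B; ``positions`` must carry x/y/z columns indexed by label.
    """
    set_a, set_b = list(set_a), list(set_b)
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("cannot compute separation for an empty set")
    shared = len(set(set_a) & set(set_b))
    pa = positions.loc[set_a, ["x", "y", "z"]].to_numpy(dtype=float)
    pb = positions.loc[set_b, ["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return shared, float(d.min(axis=1).mean())
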