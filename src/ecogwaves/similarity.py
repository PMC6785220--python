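"""First- and second-order similarity between spectral features.

First-order: per-trial Pearson correlations of two features' temporal,
spatial, or spatiotemporal activity patterns.  Second-order: trial x trial
representational similarity matrices compared by Spearman rank correlation.
Group-level inference is a one-sample t-test with a JZS default-prior Bayes
factor in favor of the null (BF01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pingouin import bayesfactor_ttest
from scipy import stats


@dataclass
class SimilarityMatrix:
    matrix: np.ndarray  # (n_trials, n_trials) pattern correlations
    vector: np.ndarray  # upper triangle, diagonal excluded


@dataclass
class GroupStats:
    t: float
    p: float
    bf01: float

    def __post_init__(self):
        if not self.bf01 > 0:
            raise ValueError("bf01 must be positive")


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row; NaN where either row is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("feature arrays must share shape")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    denom = sa * sb
    r = np.full(a.shape[0], np.nan)
    ok = denom > 0
    r[ok] = (ac[ok] * bc[ok]).sum(axis=1) / denom[ok]
    return r


def temporal_correlation(feat_a: np.ndarray, feat_b: np.ndarray) -> np.ndarray:
    """Within-trial correlation of two features' time courses.

    Inputs are (n_trials, n_times) arrays of each feature averaged over its
    own local-maxima electrodes.  Constant time courses yield NaN (flagged,
    not imputed).
    """
    a, b = np.atleast_2d(feat_a), np.atleast_2d(feat_b)
    return _rowwise_pearson(a, b)


def spatial_correlation(feat_a: np.ndarray, feat_b: np.ndarray) -> np.ndarray:
    """Within-trial correlation across the electrode dimension.

    Inputs are (n_trials, n_electrodes) per-trial mean activity vectors.
    """
    a, b = np.atleast_2d(feat_a), np.atleast_2d(feat_b)
    if a.shape[1] < 3:
        raise ValueError("need >= 3 electrodes")
    return _rowwise_pearson(a, b)


def spatiotemporal_correlation(feat_a: np.ndarray, feat_b: np.ndarray) -> np.ndarray:
    """Within-trial correlation of flattened electrode x time patterns."""
    a = np.asarray(feat_a, dtype=float)
    b = np.asarray(feat_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3:
        raise ValueError("expected (n_trials, n_electrodes, n_times) input")
    return _rowwise_pearson(a.reshape(a.shape[0], -1), b.reshape(b.shape[0], -1))


def build_rsm(patterns: np.ndarray) -> SimilarityMatrix:
    """Trial x trial correlation matrix of activity patterns.

    ``patterns`` is (n_trials, ...); trailing dimensions are flattened.
    Returns the full symmetric matrix and its vectorized upper triangle
    (diagonal excluded, length n(n-1)/2).
    """
    x = np.asarray(patterns, dtype=float).reshape(np.shape(patterns)[0], -1)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >= 3 trials")
    mat = np.corrcoef(x)
    iu = np.triu_indices(n, k=1)
    return SimilarityMatrix(matrix=mat, vector=mat[iu])


def rsa_second_order(rsm_a, rsm_b) -> float:
    """Spearman rank correlation between two similarity vectors."""
    va = rsm_a.vector if isinstance(rsm_a, SimilarityMatrix) else np.asarray(rsm_a)
    vb = rsm_b.vector if isinstance(rsm_b, SimilarityMatrix) else np.asarray(rsm_b)
    if va.shape != vb.shape:
        raise ValueError("similarity vectors must have equal length")
    rho, _ = stats.spearmanr(va, vb)
    return float(rho)


def group_inference(values, r_prior: float = np.sqrt(2) / 2) -> GroupStats:
    """One-sample t-test against zero with a JZS Bayes factor.

    BF01 favors the null; computed from the default Cauchy prior with scale
    r = sqrt(2)/2 on standardized effect size.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.allclose(x.std(ddof=1), 0.0):
        if not np.allclose(x.mean(), 0.0):
            raise ValueError("degenerate input: zero variance around nonzero mean")
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(x, 0.0)
    bf10 = float(bayesfactor_ttest(t, nx=x.size, paired=True, r=r_prior))
    return GroupStats(t=float(t), p=float(p), bf01=1.0 / bf10)
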