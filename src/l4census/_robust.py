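"""Deterministic consensus line fitting.

Robust straight-line fits are needed in two places: the current/voltage
relation that yields input resistance and resting potential under variable
holding, and the frequency/current relation that yields the rheobase
estimate. Both involve at most a handful of sweeps, so instead of a
randomized sample-consensus search we enumerate *all* two-point candidate
lines, score each by its inlier set, and refit by ordinary least squares on
the winning consensus set. This is the exhaustive limit of RANSAC: with n
points there are n(n-1)/2 candidate models, so the randomized search has
nothing left to sample and the result carries no seed.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["consensus_line_fit"]


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def consensus_line_fit(x, y, residual_threshold: float | None = None):
    """Fit ``y = slope * x + intercept`` robustly to a small point set.

    Parameters
    ----------
    x, y
        1-D arrays of equal length (n >= 2) with at least two distinct x.
    residual_threshold
        Absolute residual below which a point counts as an inlier of a
        candidate line. Default: the median absolute deviation of the
        residuals of an ordinary least-squares prefit (floored at a small
        multiple of the data scale so that exact data keep all inliers).

    Returns
    -------
    (slope, intercept) : tuple of float
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two points to fit a line")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct x values")
    if x.size == 2:
        return _ols_line(x, y)

    if residual_threshold is None:
        slope0, icpt0 = _ols_line(x, y)
        resid = np.abs(y - (slope0 * x + icpt0))
        mad = float(np.median(resid))
        scale = max(float(np.max(np.abs(y))), 1.0)
        residual_threshold = max(mad, 1e-9 * scale)

    best: tuple[int, float] | None = None  # (-n_inliers, residual sum)
    best_mask: np.ndarray | None = None
    for i, j in combinations(range(x.size), 2):
        if x[i] == x[j]:
            continue
        slope = (y[j] - y[i]) / (x[j] - x[i])
        icpt = y[i] - slope * x[i]
        resid = np.abs(y - (slope * x + icpt))
        mask = resid <= residual_threshold
        key = (-int(mask.sum()), float(resid[mask].sum()))
        if best is None or key < best:
            best = key
            best_mask = mask
    assert best_mask is not None
    if np.unique(x[best_mask]).size < 2:
        return _ols_line(x, y)
    return _ols_line(x[best_mask], y[best_mask])
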