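"""Mean-normalised, LOESS-smoothed expression-vs-depth profiles.

Sampled intensities carry arbitrary detector units that differ between
acquisitions (gain and offset are tuned per stack to fill the dynamic
range), so raw intensities are not comparable across samples.  Profiles
are therefore *mean-normalised*: each point's intensity is divided by the
mean intensity of the quantified points of its own stack, making the
profile unitless with mean 1.  The normalised points are then smoothed
against the normalised-distance coordinate ``u`` with LOESS (locally
weighted linear regression, tricube weights over the span-fraction nearest
neighbours) and evaluated on a fixed grid, which makes profiles from
different samples directly comparable node by node.

Normalisation scope is per (target, patient, stack) over quantified
pixels only, applied after the z-policy collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_SPAN = 0.3
DEFAULT_GRID = np.linspace(0.0, 3.0, 151)


@dataclass
class SmoothedProfile:
    """LOESS fit of mean-normalised intensity against normalised distance."""

    grid: np.ndarray
    fitted: np.ndarray
    span: float = DEFAULT_SPAN
    n_points: int = 0
    normalisation_factor: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.fitted = np.asarray(self.fitted, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.fitted.shape:
            raise ValueError("grid and fitted must be 1D arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def __call__(self, u) -> np.ndarray:
        """Linear interpolation of the fitted curve at arbitrary u."""
        return np.interp(np.asarray(u, dtype=float), self.grid, self.fitted)


@dataclass
class ProfileComparison:
    """Agreement between two profiles on their common grid range."""

    rmse: float
    pearson_r: float
    common_grid: np.ndarray


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of SampledPoint or a (u, intensity) pair of arrays."""
    if isinstance(points, tuple) and len(points) == 2:
        u, v = (np.asarray(a, dtype=float) for a in points)
    else:
        u = np.asarray([p.u for p in points], dtype=float)
        v = np.asarray([p.intensity for p in points], dtype=float)
    keep = np.isfinite(u)
    return u[keep], v[keep]


def mean_normalise(points):
    """Divide each intensity by the mean intensity of the point set.

    Returns ``(scaled, normalisation_factor)`` where ``scaled`` is a
    ``(u, intensity)`` array pair and the factor is the pre-normalisation
    mean (detector units).  Excluded points (non-finite ``u``) do not
    contribute.  Raises if the mean intensity is not positive.
    """
    u, v = _as_arrays(points)
    if u.size == 0:
        raise ValueError("no quantified points to normalise")
    factor = float(v.mean())
    if factor <= 0:
        raise ValueError("mean intensity must be positive (all-zero input?)")
    return (u, v / factor), factor


def loess_smooth(points, span: float = DEFAULT_SPAN, grid=None) -> SmoothedProfile:
    """LOESS-smooth intensity against u and evaluate on a fixed grid.

    Local linear regression with tricube weights over the ``span``-fraction
    nearest neighbours in ``u`` at each grid node (no robustness
    iterations).  Requires at least 10 points and at least 3 points per
    local window.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    u, v = _as_arrays(points)
    if u.size < 10:
        raise ValueError(f"need >= 10 points for LOESS, got {u.size}")
    k = int(np.ceil(span * u.size))
    if k < 3:
        raise ValueError(
            f"span {span} gives {k} point(s) per local window at grid node "
            f"{grid[0]:g}; need >= 3"
        )
    fitted = lowess(
        v, u, frac=span, it=0, xvals=grid, is_sorted=False, missing="drop"
    )
    return SmoothedProfile(
        grid=grid,
        fitted=np.asarray(fitted, dtype=float),
        span=span,
        n_points=int(u.size),
        normalisation_factor=1.0,
    )


def profile_from_points(points, span: float = DEFAULT_SPAN, grid=None) -> SmoothedProfile:
    """Mean-normalise then LOESS-smooth in one step (the standard pipeline)."""
    (u, v), factor = mean_normalise(points)
    prof = loess_smooth((u, v), span=span, grid=grid)
    prof.normalisation_factor = factor
    return prof


def _common_grid(p1: SmoothedProfile, p2: SmoothedProfile) -> np.ndarray:
    lo = max(p1.grid[0], p2.grid[0])
    hi = min(p1.grid[-1], p2.grid[-1])
    if hi <= lo:
        raise ValueError("profiles have disjoint grid ranges")
    n = max(len(p1.grid), len(p2.grid))
    return np.linspace(lo, hi, n)


def compare_profiles(p1: SmoothedProfile, p2: SmoothedProfile) -> ProfileComparison:
    """RMSE and Pearson correlation of two profiles on their overlap."""
    grid = _common_grid(p1, p2)
    f1, f2 = p1(grid), p2(grid)
    rmse = float(np.sqrt(np.mean((f1 - f2) ** 2)))
    s1, s2 = np.std(f1), np.std(f2)
    if s1 < 1e-15 and s2 < 1e-15:
        r = 1.0
    elif s1 < 1e-15 or s2 < 1e-15:
        r = 0.0
    else:
        r = float(np.corrcoef(f1, f2)[0, 1])
    return ProfileComparison(rmse=rmse, pearson_r=r, common_grid=grid)


@dataclass
class PooledProfile:
    """Node-wise mean of several profiles with a min–max envelope."""

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_profiles: int

    def __call__(self, u) -> np.ndarray:
        return np.interp(np.asarray(u, dtype=float), self.grid, self.mean)


def aggregate(profiles) -> PooledProfile:
    """Pool >= 2 profiles: per-node mean and min–max envelope on the overlap."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to aggregate")
    lo = max(p.grid[0] for p in profiles)
    hi = min(p.grid[-1] for p in profiles)
    if hi <= lo:
        raise ValueError("profiles have disjoint grid ranges")
    grid = np.linspace(lo, hi, max(len(p.grid) for p in profiles))
    vals = np.stack([p(grid) for p in profiles])
    return PooledProfile(
        grid=grid,
        mean=vals.mean(axis=0),
        lower=vals.min(axis=0),
        upper=vals.max(axis=0),
        n_profiles=len(profiles),
    )
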