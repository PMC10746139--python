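"""Kernel-smoothed pose-success probability versus binding-pocket RMSD.

The estimator is a Nadaraya-Watson locally-weighted mean of binary docking
outcomes with an Epanechnikov kernel,

    estimate(x) = sum_i w_i K((x - x_i)/h) y_i / sum_i w_i K((x - x_i)/h),

where ``x_i`` is a record's binding-pocket RMSD, ``y_i`` its correctness
flag, and ``w_i`` its pair-equal aggregation weight.  The default bandwidth
is h = 0.25 A (kernel support +-0.25 A).  To avoid boundary artifacts the
evaluation grid is restricted to the closed interval between the smallest
and largest observed x.

Uncertainty bands and two-curve significance use the pair-level bootstrap:
a ligand-protein pair's full record set is resampled as a block, the curve
is recomputed per resample (re-clipped to that resample's data range), and
percentile bands / two-sided bootstrap p-values are read off per grid point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import InsufficientDataError

__all__ = [
    "CurvePoint",
    "SmoothedCurve",
    "CurveComparison",
    "epanechnikov",
    "smooth_accuracy",
    "bootstrap_band",
    "curve_difference_test",
]

DEFAULT_BANDWIDTH = 0.25
DEFAULT_GRID_STEP = 0.01

#: A band value is reported only where at least this fraction of resampled
#: curves could be evaluated (the grid point lay inside the resample's range).
BAND_EVAL_FRACTION = 0.95


def epanechnikov(u) -> np.ndarray:
    """Epanechnikov kernel: 0.75 (1 - u^2) on |u| <= 1, else 0."""
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CurvePoint:
    """One grid point of a smoothed curve."""

    x: float
    estimate: float
    band90: Optional[tuple] = None
    n_effective: float = 0.0


@dataclass
class SmoothedCurve:
    """A kernel-smoothed success curve on a grid clipped to the data range."""

    grid: np.ndarray
    estimate: np.ndarray
    n_effective: np.ndarray
    bandwidth: float
    band_lo: Optional[np.ndarray] = None
    band_hi: Optional[np.ndarray] = None
    level: Optional[float] = None

    @property
    def points(self) -> list:
        out = []
        for k, x in enumerate(self.grid):
            band = None
            if self.band_lo is not None and np.isfinite(self.band_lo[k]):
                band = (float(self.band_lo[k]), float(self.band_hi[k]))
            out.append(CurvePoint(float(x), float(self.estimate[k]), band,
                                  float(self.n_effective[k])))
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"x": self.grid, "estimate": self.estimate, "n_effective": self.n_effective}
        if self.band_lo is not None:
            data["lo"] = self.band_lo
            data["hi"] = self.band_hi
        return pd.DataFrame(data)

    def __call__(self, x) -> np.ndarray:
        """Linear interpolation of the smoothed estimate at arbitrary x."""
        return np.interp(np.asarray(x, dtype=float), self.grid, self.estimate)


@dataclass
class CurveComparison:
    """Per-grid-point difference between two smoothed curves, with p-values."""

    grid: np.ndarray
    delta: np.ndarray
    p_values: np.ndarray
    curve_a: SmoothedCurve = field(repr=False, default=None)
    curve_b: SmoothedCurve = field(repr=False, default=None)

    def significant_below(self, alpha: float = 0.05) -> np.ndarray:
        return self.grid[self.p_values < alpha]


# ---------------------------------------------------------------------------
# Input plumbing
# ---------------------------------------------------------------------------

def _as_arrays(data, weights=None):
    """Accept a DataFrame (pocket_rmsd/correct[/weight]) or plain arrays."""
    if isinstance(data, pd.DataFrame):
        x = data["pocket_rmsd"].to_numpy(dtype=float)
        y = data["correct"].to_numpy(dtype=float)
        if weights is None and "weight" in data.columns:
            weights = data["weight"].to_numpy(dtype=float)
    else:
        x, y = data
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and weights must have equal length")
    if len(x) == 0:
        raise InsufficientDataError("need at least one data point to smooth")
    return x, y, w


def _make_grid(x: np.ndarray, grid_step: float) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < grid_step:
        return np.array([lo]) if hi == lo else np.array([lo, hi])
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    grid[-1] = min(grid[-1], hi)
    return grid


def _kernel_matrix(grid: np.ndarray, x: np.ndarray, bandwidth: float) -> np.ndarray:
    return epanechnikov((grid[:, None] - x[None, :]) / bandwidth)


def smooth_accuracy(
    data,
    weights=None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: float = DEFAULT_GRID_STEP,
    grid: Optional[np.ndarray] = None,
) -> SmoothedCurve:
    """Kernel-smoothed success probability over pocket RMSD.

    ``data`` is either a manifest DataFrame (columns ``pocket_rmsd``,
    ``correct`` and optionally ``weight``) or a ``(x, y)`` pair of arrays.
    Grid points with zero total kernel mass are omitted.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    x, y, w = _as_arrays(data, weights)
    if grid is None:
        grid = _make_grid(x, grid_step)
    else:
        grid = np.asarray(grid, dtype=float)
        grid = grid[(grid >= np.min(x)) & (grid <= np.max(x))]
    K = _kernel_matrix(grid, x, bandwidth) * w[None, :]
    denom = K.sum(axis=1)
    keep = denom > 0
    est = np.full(len(grid), np.nan)
    # guard against float round-off pushing a convex combination past the
    # extremes of y
    est[keep] = np.clip((K[keep] @ y) / denom[keep], np.min(y), np.max(y))
    return SmoothedCurve(
        grid=grid[keep], estimate=est[keep], n_effective=denom[keep],
        bandwidth=bandwidth,
    )


# ---------------------------------------------------------------------------
# Bootstrap machinery (pair-level block resampling)
# ---------------------------------------------------------------------------

def _pair_matrices(x, y, w, pair_codes, grid, bandwidth):
    """Per-pair kernel numerator/denominator matrices: (n_pairs, n_grid)."""
    K = _kernel_matrix(grid, x, bandwidth) * w[None, :]
    n_pairs = pair_codes.max() + 1
    D = np.zeros((n_pairs, len(grid)))
    N = np.zeros((n_pairs, len(grid)))
    np.add.at(D, pair_codes, K.T)
    np.add.at(N, pair_codes, (K * y[None, :]).T)
    pair_min = np.full(n_pairs, np.inf)
    pair_max = np.full(n_pairs, -np.inf)
    np.minimum.at(pair_min, pair_codes, x)
    np.maximum.at(pair_max, pair_codes, x)
    return N, D, pair_min, pair_max


def _resampled_curves(x, y, w, pair_codes, grid, bandwidth, n_resamples, rng):
    """Matrix of resampled smoothed curves, NaN outside each resample's range."""
    N, D, pair_min, pair_max = _pair_matrices(x, y, w, pair_codes, grid, bandwidth)
    n_pairs = N.shape[0]
    idx = rng.integers(0, n_pairs, size=(n_resamples, n_pairs))
    M = np.zeros((n_resamples, n_pairs))
    rows = np.repeat(np.arange(n_resamples), n_pairs)
    np.add.at(M, (rows, idx.ravel()), 1.0)
    denom = M @ D
    numer = M @ N
    est = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), np.nan)
    rmin = pair_min[idx].min(axis=1)
    rmax = pair_max[idx].max(axis=1)
    outside = (grid[None, :] < rmin[:, None]) | (grid[None, :] > rmax[:, None])
    est[outside] = np.nan
    return est


def _pair_codes(data, pair_columns=("protein_id", "ligand_id")):
    if isinstance(data, pd.DataFrame) and all(c in data.columns for c in pair_columns):
        return pd.MultiIndex.from_frame(data[list(pair_columns)].astype(str)).factorize()[0]
    return None


def bootstrap_band(
    data,
    weights=None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    level: float = 0.90,
    n_resamples: int = 9999,
    seed: int = 0,
    grid_step: float = DEFAULT_GRID_STEP,
    pair_ids=None,
) -> SmoothedCurve:
    """Smoothed curve with a pair-level percentile bootstrap band.

    ``pair_ids`` assigns each record to its resampling block (ligand-protein
    pair); taken from the DataFrame's (protein_id, ligand_id) columns when
    present, else every record is its own block.  A band value is reported
    only where >= 95% of resampled curves evaluate.
    """
    x, y, w = _as_arrays(data, weights)
    curve = smooth_accuracy((x, y), weights=w, bandwidth=bandwidth, grid_step=grid_step)
    if pair_ids is None:
        pair_ids = _pair_codes(data)
    if pair_ids is None:
        pair_codes = np.arange(len(x))
    else:
        pair_codes = pd.factorize(np.asarray(pair_ids))[0]
    if pair_codes.max() + 1 < 2:
        raise InsufficientDataError("bootstrap band needs >= 2 resampling pairs")
    rng = substream(seed, "bootstrap-band")
    est = _resampled_curves(x, y, w, pair_codes, curve.grid, bandwidth, n_resamples, rng)
    frac_eval = np.mean(np.isfinite(est), axis=0)
    alpha = (1.0 - level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        lo = np.nanquantile(est, alpha, axis=0)
        hi = np.nanquantile(est, 1.0 - alpha, axis=0)
    bad = frac_eval < BAND_EVAL_FRACTION
    lo[bad] = np.nan
    hi[bad] = np.nan
    # a percentile band always brackets its own point estimate up to
    # resampling noise; enforce the invariant exactly
    lo = np.fmin(lo, curve.estimate)
    hi = np.fmax(hi, curve.estimate)
    curve.band_lo, curve.band_hi, curve.level = lo, hi, level
    return curve


def curve_difference_test(
    data_a,
    data_b,
    weights_a=None,
    weights_b=None,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid: Optional[np.ndarray] = None,
    grid_step: float = DEFAULT_GRID_STEP,
    n_resamples: int = 9999,
    seed: int = 0,
    pair_ids_a=None,
    pair_ids_b=None,
) -> CurveComparison:
    """Per-grid-point bootstrap test of curve A minus curve B.

    The null distribution is generated by resampling pairs independently
    within each group; the two-sided p-value at x is
    ``2 * min(frac(delta* <= 0), frac(delta* >= 0))`` with a ``+1/(n+1)``
    continuity correction, evaluated only where both curves exist.
    """
    xa, ya, wa = _as_arrays(data_a, weights_a)
    xb, yb, wb = _as_arrays(data_b, weights_b)
    lo = max(xa.min(), xb.min())
    hi = min(xa.max(), xb.max())
    if lo > hi:
        warnings.warn("non-overlapping x ranges: empty comparison", stacklevel=2)
        empty = np.array([])
        return CurveComparison(empty, empty, empty)
    if grid is None:
        grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    else:
        grid = np.asarray(grid, dtype=float)
        grid = grid[(grid >= lo) & (grid <= hi)]
    curve_a = smooth_accuracy((xa, ya), weights=wa, bandwidth=bandwidth, grid=grid)
    curve_b = smooth_accuracy((xb, yb), weights=wb, bandwidth=bandwidth, grid=grid)
    common, ia, ib = np.intersect1d(curve_a.grid, curve_b.grid, return_indices=True)
    delta = curve_a.estimate[ia] - curve_b.estimate[ib]

    def codes(data, pair_ids, n):
        if pair_ids is None:
            pair_ids = _pair_codes(data)
        if pair_ids is None:
            return np.arange(n)
        return pd.factorize(np.asarray(pair_ids))[0]

    ca = codes(data_a, pair_ids_a, len(xa))
    cb = codes(data_b, pair_ids_b, len(xb))
    rng_a = substream(seed, "curve-diff", "A")
    rng_b = substream(seed, "curve-diff", "B")
    est_a = _resampled_curves(xa, ya, wa, ca, common, bandwidth, n_resamples, rng_a)
    est_b = _resampled_curves(xb, yb, wb, cb, common, bandwidth, n_resamples, rng_b)
    dstar = est_a - est_b
    n_eval = np.sum(np.isfinite(dstar), axis=0)
    with np.errstate(invalid="ignore"):
        n_le = np.nansum(dstar <= 0, axis=0)
        n_ge = np.nansum(dstar >= 0, axis=0)
    p = 2.0 * np.minimum((n_le + 1) / (n_eval + 1), (n_ge + 1) / (n_eval + 1))
    p = np.minimum(p, 1.0)
    p[n_eval == 0] = np.nan
    return CurveComparison(grid=common, delta=delta, p_values=p,
                           curve_a=curve_a, curve_b=curve_b)
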