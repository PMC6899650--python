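"""Distance-based summary functions for planar point patterns.

Implements the four summary statistics used throughout the analysis:

* pair correlation function g(r) — intensity-normalised neighbour density,
  1 under complete spatial randomness (CSR), > 1 aggregated, < 1 segregated;
* Ripley's K via its variance-stabilised L-function, L(r) = sqrt(K/π),
  equal to r under CSR;
* the O-ring statistic O(r) = λ·g(r), the absolute neighbour density in
  annuli;
* the nearest-neighbour distance CDF D(r).

Estimation conventions: distances are binned with a box kernel of full
width equal to the bandwidth h, on a grid r_k = h/2 + k·h; g and K use the
translation edge correction |W ∩ W_shift|; D uses the border (reduced
sample) correction.  After binning, g and O are smoothed with a centred
moving average over ``smoothing_span`` grid steps, so a span of 3 realises
"three-bandwidth" smoothing; span 1 leaves the estimate untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import UndefinedCurveError
from .geometry import ObservationWindow


@dataclass(frozen=True)
class DistanceGrid:
    """Distance grid for summary-function estimation.

    ``r_values`` are the bin centres h/2, 3h/2, ... up to ``r_max``; the
    grid step equals the bandwidth so a ``smoothing_span`` of s averages
    over s bandwidths.
    """

    bandwidth: float = 0.1
    r_max: float = 2.5
    smoothing_span: int = 3

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.r_max < self.bandwidth:
            raise ValueError("r_max must be >= bandwidth")
        if self.smoothing_span < 1:
            raise ValueError("smoothing_span must be >= 1")

    @property
    def r_values(self) -> np.ndarray:
        n_bins = int(np.floor(self.r_max / self.bandwidth + 1e-9))
        return self.bandwidth / 2 + self.bandwidth * np.arange(n_bins)


@dataclass
class SummaryCurve:
    """A distance-indexed summary function, optionally with an MC envelope."""

    kind: str  # "pcf" | "L" | "oring" | "nn"
    r: np.ndarray
    values: np.ndarray
    n_points: int | tuple[int, int]
    bandwidth: float
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None
    n_sims: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"r_m": self.r, "value": self.values})
        df["envelope_lo"] = self.envelope_lo if self.envelope_lo is not None else np.nan
        df["envelope_hi"] = self.envelope_hi if self.envelope_hi is not None else np.nan
        df["kind"] = self.kind
        df["n_sims"] = self.n_sims if self.n_sims is not None else 0
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def value_at(self, r: float) -> float:
        """Linear interpolation of the curve at distance r."""
        return float(np.interp(r, self.r, self.values))


def moving_average(values: np.ndarray, span: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if span == 1:
        return values.copy()
    lo, hi = (span - 1) // 2, span // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for k in range(n):
        out[k] = values[max(0, k - lo) : min(n, k + hi + 1)].mean()
    return out


def _as_points(pattern) -> np.ndarray:
    pts = np.asarray(pattern, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("pattern must be an (n, 2) array of coordinates")
    return pts


def _warn_r_max(grid: DistanceGrid, window: ObservationWindow) -> None:
    if grid.r_max > 0.25 * window.diameter + 1e-12:
        warnings.warn(
            f"r_max = {grid.r_max} exceeds a quarter of the window diameter "
            f"({window.diameter:.3f} m); estimates at large r are unreliable",
            stacklevel=3,
        )


def _cross_pair_weights(
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    window: ObservationWindow,
    r_cut: float,
    univariate: bool,
):
    """Distances and translation-correction weights 1/|W ∩ W_Δ| for ordered pairs.

    For the univariate case each unordered pair is returned once with its
    weight doubled (the displacement correction is symmetric).
    """
    if univariate:
        tree = cKDTree(pts_a)
        pairs = tree.query_pairs(r_cut, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty(0), np.empty(0)
        diff = pts_a[pairs[:, 0]] - pts_a[pairs[:, 1]]
        mult = 2.0
    else:
        tree_a, tree_b = cKDTree(pts_a), cKDTree(pts_b)
        pairs_list = tree_a.query_ball_tree(tree_b, r_cut)
        ia = np.repeat(np.arange(len(pts_a)), [len(p) for p in pairs_list])
        ib = np.concatenate([np.asarray(p, int) for p in pairs_list]) if len(ia) else np.empty(0, int)
        if len(ia) == 0:
            return np.empty(0), np.empty(0)
        diff = pts_a[ia] - pts_b[ib]
        d0 = np.hypot(diff[:, 0], diff[:, 1])
        keep = d0 > 0  # identical coordinates across patterns contribute nothing
        diff = diff[keep]
        mult = 1.0
    d = np.hypot(diff[:, 0], diff[:, 1])
    areas = window.translation_area(diff[:, 0], diff[:, 1])
    w = mult / areas
    return d, w


def _binned_sum(d: np.ndarray, w: np.ndarray, grid: DistanceGrid) -> np.ndarray:
    """Sum of weights per distance bin [k·h, (k+1)·h)."""
    n_bins = len(grid.r_values)
    sums = np.zeros(n_bins)
    if len(d):
        idx = np.floor(d / grid.bandwidth).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(sums, idx[ok], w[ok])
    return sums


def estimate_pcf(
    pattern, window: ObservationWindow, grid: DistanceGrid | None = None
) -> SummaryCurve:
    """Estimate the univariate pair correlation function g(r).

    Box-kernel estimate with translation edge correction, normalised by
    the unbiased intensity-squared estimate n(n−1)/|W|² so the CSR
    expectation is 1 at every r, then moving-average smoothed over
    ``grid.smoothing_span`` bandwidths.
    """
    grid = grid or DistanceGrid()
    pts = _as_points(pattern)
    n = len(pts)
    if n < 2:
        raise UndefinedCurveError("PCF needs at least 2 points")
    _warn_r_max(grid, window)
    r = grid.r_values
    d, w = _cross_pair_weights(pts, pts, window, r[-1] + grid.bandwidth / 2, univariate=True)
    sums = _binned_sum(d, w, grid)
    lam2 = n * (n - 1) / window.area**2
    g = sums / (2 * np.pi * r * grid.bandwidth * lam2)
    g = moving_average(g, grid.smoothing_span)
    return SummaryCurve("pcf", r, g, n, grid.bandwidth)


def estimate_pcf_bivariate(
    pattern_a, pattern_b, window: ObservationWindow, grid: DistanceGrid | None = None
) -> SummaryCurve:
    """Cross-type pair correlation g_ab(r) (symmetric estimator).

    Normalised by λ_a·λ_b = n_a·n_b/|W|²; 1 when the two patterns are
    independent, > 1 when specimens of b aggregate around a (and vice
    versa — the translation-corrected estimator is symmetric in a and b).
    """
    grid = grid or DistanceGrid()
    pts_a, pts_b = _as_points(pattern_a), _as_points(pattern_b)
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise UndefinedCurveError("bivariate PCF needs non-empty patterns")
    _warn_r_max(grid, window)
    r = grid.r_values
    d, w = _cross_pair_weights(pts_a, pts_b, window, r[-1] + grid.bandwidth / 2, univariate=False)
    sums = _binned_sum(d, w, grid)
    lam2 = len(pts_a) * len(pts_b) / window.area**2
    g = sums / (2 * np.pi * r * grid.bandwidth * lam2)
    g = moving_average(g, grid.smoothing_span)
    return SummaryCurve("pcf", r, g, (len(pts_a), len(pts_b)), grid.bandwidth)


def estimate_L(
    pattern, window: ObservationWindow, grid: DistanceGrid | None = None
) -> SummaryCurve:
    """Estimate L(r) = sqrt(K(r)/π) from the translation-corrected K.

    K is evaluated cumulatively at the grid's bin centres; no smoothing is
    applied (K is already a cumulative, hence smooth, statistic).
    """
    grid = grid or DistanceGrid()
    pts = _as_points(pattern)
    n = len(pts)
    if n < 2:
        raise UndefinedCurveError("L-function needs at least 2 points")
    _warn_r_max(grid, window)
    r = grid.r_values
    d, w = _cross_pair_weights(pts, pts, window, r[-1], univariate=True)
    lam2 = n * (n - 1) / window.area**2
    if len(d):
        order = np.argsort(d)
        d_sorted, w_sorted = d[order], np.cumsum(w[order])
        idx = np.searchsorted(d_sorted, r, side="right")
        K = np.where(idx > 0, w_sorted[np.maximum(idx - 1, 0)], 0.0) / lam2
    else:
        K = np.zeros_like(r)
    L = np.sqrt(K / np.pi)
    return SummaryCurve("L", r, L, n, grid.bandwidth)


def estimate_oring(
    pattern, window: ObservationWindow, grid: DistanceGrid | None = None
) -> SummaryCurve:
    """O-ring statistic O(r) = λ·g(r): neighbour density in annuli (m⁻²)."""
    grid = grid or DistanceGrid()
    pts = _as_points(pattern)
    g = estimate_pcf(pts, window, grid)
    lam = len(pts) / window.area
    return SummaryCurve("oring", g.r, lam * g.values, len(pts), grid.bandwidth)


def estimate_nn(
    pattern, window: ObservationWindow, grid: DistanceGrid | None = None
) -> SummaryCurve:
    """Nearest-neighbour distance CDF D(r) with border correction.

    Reduced-sample estimator: D(r) = #{i : d_i ≤ r ≤ b_i} / #{i : b_i ≥ r}
    with d_i the nearest-neighbour distance and b_i the distance to the
    window boundary; monotonised by a running maximum and clipped to [0, 1].
    """
    grid = grid or DistanceGrid()
    pts = _as_points(pattern)
    n = len(pts)
    if n < 2:
        raise UndefinedCurveError("nearest-neighbour function needs at least 2 points")
    r = grid.r_values
    tree = cKDTree(pts)
    d_nn = tree.query(pts, k=2)[0][:, 1]
    b = window.boundary_distance(pts[:, 0], pts[:, 1])
    denom = (b[None, :] >= r[:, None]).sum(axis=1).astype(float)
    numer = ((d_nn[None, :] <= r[:, None]) & (b[None, :] >= r[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, numer / denom, np.nan)
    # carry the last defined value forward, then enforce monotonicity
    last = 0.0
    for k in range(len(D)):
        if np.isnan(D[k]):
            D[k] = last
        else:
            last = D[k]
    D = np.clip(np.maximum.accumulate(D), 0.0, 1.0)
    return SummaryCurve("nn", r, D, n, grid.bandwidth)


ESTIMATORS = {
    "pcf": estimate_pcf,
    "L": estimate_L,
    "oring": estimate_oring,
    "nn": estimate_nn,
}
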