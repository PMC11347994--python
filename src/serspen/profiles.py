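"""Depth- and time-resolved quantification of penetration.

Content (MCR-ALS abundance of a matched component, or a characteristic-peak
intensity when unmixing is skipped) is averaged over all lateral pixels at
the same depth to give a depth profile per acquisition time; profile means
over time give the total-content penetration curve, smoothed with a cubic
regression B-spline flexible enough to express the non-monotone weakening
phase.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline, make_lsq_spline

from .errors import DomainError
from .types import HyperMap, Spectrum

__all__ = [
    "DepthProfile",
    "PenetrationCurve",
    "peak_intensity",
    "depth_profile",
    "total_content_curve",
    "bspline_trend",
]


@dataclass
class DepthProfile:
    """Mean content per contiguous depth bin at one acquisition time."""

    depth_bins: list[tuple[float, float]]
    mean_content: np.ndarray
    time_h: float
    pixel_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean_content = np.asarray(self.mean_content, dtype=float)
        if len(self.depth_bins) != self.mean_content.size:
            raise DomainError("one mean per bin required")
        for (lo, hi), (lo2, _) in zip(self.depth_bins, self.depth_bins[1:]):
            if not (hi == lo2 and hi > lo):
                raise DomainError("bins must be contiguous and non-overlapping")

    @property
    def bin_centers_um(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.depth_bins])


@dataclass
class PenetrationCurve:
    """Total content vs time, with an optional smoothed trend."""

    times_h: np.ndarray
    total_content: np.ndarray
    trend_times_h: np.ndarray | None = None
    trend: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.total_content = np.asarray(self.total_content, dtype=float)
        if self.times_h.size != self.total_content.size:
            raise DomainError("times and contents must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.total_content < 0):
            raise DomainError("contents must be >= 0")


def peak_intensity(spec: Spectrum, center_cm1: float, half_window_cm1: float = 10.0) -> float:
    """Maximum intensity within ``center +- half_window`` cm^-1.

    The spectrum is expected to be baseline-corrected already (raw SERS
    spectra would report fluorescence, not the band).
    """
    nu = spec.axis.values
    mask = (nu >= center_cm1 - half_window_cm1) & (nu <= center_cm1 + half_window_cm1)
    if not np.any(mask):
        raise DomainError(
            f"window [{center_cm1 - half_window_cm1}, {center_cm1 + half_window_cm1}] "
            "does not intersect the axis"
        )
    return float(np.max(spec.intensities[mask]))


def depth_profile(
    content: np.ndarray,
    cube: HyperMap,
    bin_um: float | None = None,
) -> DepthProfile:
    """Mean content over all lateral pixels per depth bin.

    Bins of width ``bin_um`` (default: one grid row) tile ``[0, extent]``;
    the last bin is closed so the deepest row is included.  Bins that
    contain no pixel report 0 with a count of 0.
    """
    content = np.asarray(content, dtype=float).ravel()
    if content.size != cube.n_pixels:
        raise DomainError("content vector length does not match the cube grid")
    extent = cube.depth_extent_um
    if bin_um is None:
        bin_um = cube.depth_step_um
    if not (0 < bin_um <= max(extent, cube.depth_step_um)):
        raise DomainError("bin_um must be positive and no larger than the depth extent")
    n_bins = max(1, int(np.ceil(extent / bin_um))) if extent > 0 else 1
    depths = cube.pixel_depths_um()
    idx = np.minimum((depths / bin_um).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=content, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    bins = [(k * bin_um, (k + 1) * bin_um) for k in range(n_bins)]
    return DepthProfile(
        depth_bins=bins, mean_content=means, time_h=cube.time_h, pixel_counts=counts
    )


def total_content_curve(
    profiles: Sequence[DepthProfile],
    mode: str = "bins",
    spline_df: int | None = None,
    trend_points: int = 200,
) -> PenetrationCurve:
    """Average each profile into one total-content value per time point.

    ``mode='bins'`` takes the plain mean over depth bins; ``mode='pixels'``
    weights bins by their pixel counts.  With ``spline_df`` set, a cubic
    regression B-spline trend is evaluated on a fine time grid.
    """
    if len(profiles) < 2:
        raise DomainError("need at least two time points")
    if mode not in ("bins", "pixels"):
        raise DomainError("mode must be 'bins' or 'pixels'")
    bins0 = profiles[0].depth_bins
    for p in profiles[1:]:
        if p.depth_bins != bins0:
            raise DomainError("profiles have inconsistent depth binning")
    times = np.array([p.time_h for p in profiles])
    order = np.argsort(times)
    times = times[order]
    if np.any(np.diff(times) <= 0):
        raise DomainError("profiles must have distinct acquisition times")
    totals = np.empty(times.size)
    for out_i, i in enumerate(order):
        p = profiles[i]
        if mode == "bins":
            totals[out_i] = float(p.mean_content.mean())
        else:
            counts = p.pixel_counts
            if counts is None or counts.sum() == 0:
                raise DomainError("pixel-weighted mode requires pixel counts")
            totals[out_i] = float(np.sum(p.mean_content * counts) / counts.sum())
    trend_t = trend_y = None
    if spline_df is not None:
        trend_t = np.linspace(times[0], times[-1], trend_points)
        trend_y = bspline_trend(times, totals, spline_df, trend_t)
    return PenetrationCurve(
        times_h=times, total_content=totals, trend_times_h=trend_t, trend=trend_y
    )


def bspline_trend(
    x: np.ndarray, y: np.ndarray, df: int, grid: np.ndarray
) -> np.ndarray:
    """Regression B-spline fit with ``df`` basis functions, evaluated on ``grid``.

    Cubic whenever ``df >= 4`` (degree ``df - 1`` below that); interior
    knots at quantiles of ``x``.  ``df == n`` interpolates the data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = x.size
    if y.size != n:
        raise DomainError("x and y must have equal length")
    if np.any(np.diff(x) <= 0):
        raise DomainError("x must be strictly increasing")
    if not (2 <= df <= n):
        raise DomainError(f"df must lie in [2, n={n}]")
    k = min(3, df - 1)
    if df == n:
        spl = make_interp_spline(x, y, k=k)
    else:
        n_interior = df - (k + 1)
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
        else:
            interior = np.array([])
        t = np.r_[[x[0]] * (k + 1), interior, [x[-1]] * (k + 1)]
        spl: BSpline = make_lsq_spline(x, y, t, k=k)
    return np.asarray(spl(grid), dtype=float)
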