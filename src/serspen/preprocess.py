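"""Spectral preprocessing: axis construction, baseline correction,
normalization and resampling.

Fluorescence from fruit pulp dominates raw SERS spectra; before any
similarity or unmixing step the broad background is removed with asymmetric
least squares (AsLS) — a Whittaker smoother whose weights are iteratively
biased so the fit hugs the spectrum from below, leaving the sharp Raman
bands in the residual.
"""
from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import DomainError
from .types import Spectrum, WavenumberAxis

__all__ = [
    "build_axis",
    "asls_baseline",
    "baseline_correct",
    "baseline_correct_matrix",
    "normalize_spectrum",
    "normalize_rows",
    "resample_spectrum",
]


def build_axis(start_cm1: float, stop_cm1: float, n_channels: int) -> WavenumberAxis:
    """Uniform wavenumber grid with endpoints included."""
    if not stop_cm1 > start_cm1:
        raise DomainError("stop_cm1 must exceed start_cm1")
    if n_channels < 2:
        raise DomainError("n_channels must be at least 2")
    return WavenumberAxis(np.linspace(start_cm1, stop_cm1, int(n_channels)))


def asls_baseline(
    y: np.ndarray,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    n_iter: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares baseline of a 1-D signal.

    Minimises ``sum w_i (y_i - z_i)^2 + smoothness * sum (D2 z)^2`` where the
    weights are ``asymmetry`` above the current baseline and
    ``1 - asymmetry`` below it, refined for ``n_iter`` rounds.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise DomainError("asls_baseline expects a 1-D signal")
    if not np.all(np.isfinite(y)):
        raise DomainError("signal must be finite")
    if smoothness <= 0:
        raise DomainError("smoothness must be positive")
    if not (0 < asymmetry < 1):
        raise DomainError("asymmetry must lie in (0, 1)")
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    n = y.size
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (d2.T @ d2)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        lhs = sparse.diags(w, format="csc") + penalty
        z = spsolve(lhs, w * y)
        w = np.where(y > z, asymmetry, 1.0 - asymmetry)
    return z


def baseline_correct(
    spec: Spectrum,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    n_iter: int = 10,
) -> Spectrum:
    """Subtract the AsLS baseline estimate from a spectrum.

    Negative residuals are retained; clip explicitly before any stage that
    requires non-negativity (MCR-ALS).
    """
    z = asls_baseline(spec.intensities, smoothness, asymmetry, n_iter)
    return spec.copy_with(spec.intensities - z)


def baseline_correct_matrix(
    X: np.ndarray,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    n_iter: int = 10,
) -> np.ndarray:
    """Row-wise AsLS baseline correction of a spectral matrix."""
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i] = X[i] - asls_baseline(X[i], smoothness, asymmetry, n_iter)
    return out


_NORM_MODES = ("max", "l2", "area")


def normalize_spectrum(spec: Spectrum, mode: str = "l2") -> Spectrum:
    """Scale a spectrum so its max, l2 norm, or trapezoidal area equals 1."""
    if mode not in _NORM_MODES:
        raise DomainError(f"mode must be one of {_NORM_MODES}")
    y = spec.intensities
    if mode == "max":
        norm = float(np.max(y))
    elif mode == "l2":
        norm = float(np.linalg.norm(y))
    else:
        norm = float(np.trapezoid(y, spec.axis.values))
    if norm <= 0 or not np.isfinite(norm):
        raise DomainError(f"cannot normalize: {mode} norm is {norm}")
    return spec.copy_with(y / norm)


def normalize_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise l2 normalization; all-zero rows are left at zero."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return X / safe


def resample_spectrum(spec: Spectrum, target: WavenumberAxis) -> Spectrum:
    """Linear interpolation onto ``target``; extrapolation is refused."""
    src = spec.axis.values
    tgt = target.values
    if tgt[0] < src[0] - 1e-12 or tgt[-1] > src[-1] + 1e-12:
        raise DomainError(
            f"target range [{tgt[0]}, {tgt[-1]}] not contained in "
            f"source range [{src[0]}, {src[-1]}]; extrapolation refused"
        )
    return Spectrum(target, np.interp(tgt, src, spec.intensities))
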