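"""Vertex component analysis (VCA) endmember extraction and matching.

VCA exploits the geometry of the linear mixing model: mixed pixel spectra
live inside a simplex whose vertices are the pure-component spectra.  The
algorithm repeatedly projects the data onto directions orthogonal to the
endmembers found so far and takes the extreme pixel as the next vertex, so
every extracted endmember is an actual pixel spectrum (pure-pixel
assumption).

The SNR estimate decides between two dimensionality reductions, following
the canonical algorithm: above ``15 + 10*log10(p)`` dB the data are reduced
with an uncentered rank-p SVD and projectively scaled; below it they are
mean-centered, reduced to p-1 principal components and lifted back with a
constant coordinate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .errors import DegenerateInputError, DomainError
from .types import HyperMap, ReferenceSpectrum, Spectrum

__all__ = [
    "EndmemberSet",
    "AbundanceMap",
    "estimate_snr",
    "run_vca",
    "spectral_angle",
    "match_endmembers",
    "abundance_nnls",
    "BACKGROUND_LABEL",
]

BACKGROUND_LABEL = "background"

#: sentinel returned by estimate_snr when the residual is numerically zero
SNR_CAP_DB = 300.0


@dataclass
class EndmemberSet:
    """Extracted or library endmember spectra, rows of ``S``."""

    S: np.ndarray
    source_pixel_indices: np.ndarray | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if S.shape[0] < 1 or not np.all(np.isfinite(S)):
            raise DomainError("endmember matrix must be non-empty and finite")
        self.S = S
        if self.source_pixel_indices is not None:
            idx = np.asarray(self.source_pixel_indices, dtype=int)
            if idx.size != S.shape[0]:
                raise DomainError("one source pixel index per endmember required")
            if len(set(idx.tolist())) != idx.size:
                raise DomainError("duplicate source pixel indices")
            self.source_pixel_indices = idx
        if self.names is not None and len(self.names) != S.shape[0]:
            raise DomainError("one name per endmember required")

    @property
    def n_endmembers(self) -> int:
        return int(self.S.shape[0])


@dataclass
class AbundanceMap:
    """Per-pixel non-negative coefficients against an endmember set."""

    C: np.ndarray
    source: HyperMap | None = None

    def __post_init__(self) -> None:
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if not np.all(np.isfinite(C)):
            raise DomainError("abundances must be finite")
        if np.any(C < -1e-12):
            raise DomainError("abundances must be non-negative")
        self.C = np.maximum(C, 0.0)

    def component_image(self, k: int) -> np.ndarray:
        if self.source is None:
            raise DomainError("no source cube attached")
        return self.source.as_image(self.C[:, k])


def estimate_snr(X: np.ndarray, p: int) -> float:
    """Signal-to-noise estimate (dB) from the rank-p principal subspace.

    The energy captured by the top-p singular directions is attributed to
    signal plus its share of isotropic noise; the residual energy,
    spread over the remaining ``n_channels - p`` directions, calibrates the
    per-dimension noise level.  Returns the ``SNR_CAP_DB`` sentinel for
    numerically exact rank-p data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_pix, n_chan = X.shape
    if not (0 < p < min(n_pix, n_chan)):
        raise DomainError(f"p must satisfy 0 < p < min(n_pixels, n_channels) = {min(n_pix, n_chan)}")
    sv = np.linalg.svd(X, compute_uv=False)
    total = float(np.sum(sv**2)) / n_pix  # mean per-pixel energy
    if total == 0.0:
        raise DegenerateInputError("all-zero spectral matrix; SNR undefined")
    p_sub = float(np.sum(sv[:p] ** 2)) / n_pix
    p_res = total - p_sub
    if p_res <= 1e-18 * total:
        return SNR_CAP_DB
    noise_per_dim = p_res / (n_chan - p)
    p_noise = n_chan * noise_per_dim
    p_signal = p_sub - p * noise_per_dim
    if p_signal <= 0:
        p_signal = np.finfo(float).tiny
    return float(10.0 * np.log10(p_signal / p_noise))


def _projective_subspace(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """High-SNR path: uncentered rank-p SVD + projective scaling.

    Returns the scaled p-dim coordinates used for vertex search and the
    rank-p reconstruction of every pixel (the denoised spectra)."""
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    Ud = Vt[:p]  # (p, n_chan)
    Xd = X @ Ud.T  # (n_pix, p)
    recon = Xd @ Ud
    u = Xd.mean(axis=0)
    denom = Xd @ u
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    return Xd / denom[:, None], recon


def _affine_subspace(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Low-SNR path: mean-centered rank-(p-1) PCA lifted by a constant."""
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xd = Xc @ Vt[: p - 1].T  # (n_pix, p-1)
    recon = Xd @ Vt[: p - 1] + mu
    c = float(np.max(np.linalg.norm(Xd, axis=1))) or 1.0
    return np.column_stack([Xd, np.full(X.shape[0], c)]), recon


def run_vca(X: np.ndarray, p: int, seed: int = 0) -> EndmemberSet:
    """Extract ``p`` endmembers; each is an actual pixel spectrum of ``X``.

    Deterministic for a given ``seed`` (the orthogonal probe directions are
    drawn from it); ties in the extreme-pixel search resolve to the lowest
    pixel index, and a pixel is never selected twice.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_pix, n_chan = X.shape
    if not np.all(np.isfinite(X)):
        raise DomainError("spectral matrix must be finite")
    if not (1 <= p <= min(n_pix, n_chan)):
        raise DomainError(f"p must lie in [1, {min(n_pix, n_chan)}]")
    if np.allclose(X, X[0], atol=1e-12 * max(1.0, float(np.abs(X).max()))):
        raise DegenerateInputError("all pixels identical; no simplex to analyse")

    if p == 1:
        mu = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - mu, full_matrices=False)
        proj = (X - mu) @ Vt[0]
        k = int(np.argmax(np.abs(proj)))
        return EndmemberSet(S=_fix_sign(X[[k]]), source_pixel_indices=np.array([k]))

    snr = estimate_snr(X, p) if p < min(n_pix, n_chan) else SNR_CAP_DB
    snr_threshold = 15.0 + 10.0 * np.log10(p)
    if snr > snr_threshold:
        Y, recon = _projective_subspace(X, p)
    else:
        Y, recon = _affine_subspace(X, p)

    rng = np.random.default_rng(seed)
    A = np.zeros((p, p))
    A[p - 1, 0] = 1.0
    indices = np.empty(p, dtype=int)
    taken = np.zeros(n_pix, dtype=bool)
    for i in range(p):
        w = rng.standard_normal(p)
        f = w - A @ (np.linalg.pinv(A) @ w)
        norm = np.linalg.norm(f)
        if norm < 1e-12:  # probe fell in span(A); redraw deterministically
            w = rng.standard_normal(p)
            f = w - A @ (np.linalg.pinv(A) @ w)
            norm = np.linalg.norm(f)
        f = f / norm
        v = np.abs(Y @ f)
        v[taken] = -np.inf
        k = int(np.argmax(v))
        indices[i] = k
        taken[k] = True
        A[:, i] = Y[k]
    # endmembers are the selected pixels' signal-subspace reconstructions:
    # identical to the raw pixels for exact low-rank data, denoised otherwise
    return EndmemberSet(S=_fix_sign(recon[indices]), source_pixel_indices=indices)


def _fix_sign(S: np.ndarray) -> np.ndarray:
    """Flip each endmember so the channel of maximal |value| is positive."""
    S = S.copy()
    for row in S:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return S


def spectral_angle(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> float:
    """Angle (radians, in [0, pi]) between two spectra; scale-invariant."""
    va = a.intensities if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    vb = b.intensities if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise DomainError("spectra must have equal length")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise DomainError("spectral angle undefined for a zero vector")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosang))


def match_endmembers(
    E: EndmemberSet,
    refs: Sequence[ReferenceSpectrum],
    max_angle: float = 0.2,
) -> EndmemberSet:
    """Label endmembers by optimal one-to-one assignment to references.

    Minimises the total spectral angle (Hungarian algorithm); assignments
    worse than ``max_angle`` radians, and endmembers left without a
    reference, are labeled ``background``.  Each reference is used at most
    once.
    """
    if not refs:
        raise DomainError("need at least one reference spectrum")
    p, r = E.n_endmembers, len(refs)
    cost = np.empty((p, r))
    for i in range(p):
        for j in range(r):
            cost[i, j] = spectral_angle(E.S[i], refs[j].spectrum.intensities)
    rows, cols = linear_sum_assignment(cost)
    names = [BACKGROUND_LABEL] * p
    for i, j in zip(rows, cols):
        if cost[i, j] <= max_angle:
            names[i] = refs[j].name
    return EndmemberSet(S=E.S, source_pixel_indices=E.source_pixel_indices, names=names)


def abundance_nnls(X: np.ndarray, E: EndmemberSet, source: HyperMap | None = None) -> AbundanceMap:
    """Exact per-pixel non-negative least squares against the endmembers."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S = E.S
    if X.shape[1] != S.shape[1]:
        raise DomainError("pixel spectra and endmembers have different channel counts")
    if np.all(np.linalg.norm(S, axis=1) == 0):
        raise DomainError("degenerate endmember set (all zero)")
    A = S.T  # (n_chan, p)
    C = np.empty((X.shape[0], S.shape[0]))
    for i in range(X.shape[0]):
        C[i], _ = nnls(A, X[i])
    return AbundanceMap(C=C, source=source)
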