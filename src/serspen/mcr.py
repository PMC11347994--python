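"""MCR-ALS: multivariate curve resolution by alternating least squares.

Refines a bilinear factorization ``X ~ C @ S`` under non-negativity of both
factors, alternating exact NNLS solves — per-pixel for the concentrations
``C`` given the spectra ``S``, per-channel for ``S`` given ``C`` — so the
lack of fit (LOF) is non-increasing by construction.  After each spectral
update every row of ``S`` is rescaled to unit maximum, with the scale
absorbed into ``C``, which fixes the intensity ambiguity of the bilinear
model without changing the reconstruction.

Only non-negativity is imposed: no unimodality or closure, because
penetration depth profiles are legitimately non-monotone.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import DegenerateInputError, DomainError
from .unmix import AbundanceMap, EndmemberSet

__all__ = ["McrResult", "run_mcr_als", "lack_of_fit"]


@dataclass
class McrResult:
    C: AbundanceMap
    S: EndmemberSet
    lof_trace: np.ndarray
    n_iter: int
    converged: bool


def lack_of_fit(X: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    """Standard MCR diagnostic: ``100 * sqrt(sum (X - C S)^2 / sum X^2)``."""
    X = np.asarray(X, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    denom = float(np.sum(X**2))
    if denom == 0.0:
        raise DomainError("lack of fit undefined for an all-zero matrix")
    resid = X - C @ S
    return float(100.0 * np.sqrt(np.sum(resid**2) / denom))


def _nnls_rows(design: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||B[i] - design @ x||, x >= 0 for every row of B."""
    out = np.empty((B.shape[0], design.shape[1]))
    for i in range(B.shape[0]):
        out[i], _ = nnls(design, B[i])
    return out


def run_mcr_als(
    X: np.ndarray,
    S_init: EndmemberSet,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> McrResult:
    """Alternating NNLS refinement of (C, S) from an initial spectra guess.

    ``X`` is clipped to be non-negative (the bilinear model assumes
    non-negative intensities; baseline-corrected spectra can dip below 0).
    Stops when the relative LOF change drops below ``tol`` or after
    ``max_iter`` iterations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if tol <= 0:
        raise DomainError("tol must be positive")
    if max_iter < 1:
        raise DomainError("max_iter must be >= 1")
    if not np.any(X > 0):
        raise DegenerateInputError("all-zero spectral matrix")
    S = np.maximum(np.atleast_2d(np.asarray(S_init.S, dtype=float)), 0.0)
    if np.any(np.linalg.norm(S, axis=1) == 0):
        raise DomainError("S_init rows must be non-zero")
    if S.shape[1] != X.shape[1]:
        raise DomainError("S_init channel count does not match X")
    Xnn = np.maximum(X, 0.0)

    S = _normalize_rows_max(S.copy())
    C = None
    trace: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        C = _nnls_rows(S.T, Xnn)  # per-pixel: min ||x - c S||, c >= 0
        St = _nnls_rows(C, Xnn.T)  # per-channel: min ||X[:,j] - C s_j||, s_j >= 0
        S = St.T  # (p, n_chan)
        S, C = _renormalize(S, C)
        trace.append(lack_of_fit(Xnn, C, S))
        if trace[-1] < 1e-9:  # numerically exact factorization
            converged = True
            break
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) / trace[-2] < tol:
            converged = True
            break
    return McrResult(
        C=AbundanceMap(C=C),
        S=EndmemberSet(S=S, names=S_init.names),
        lof_trace=np.asarray(trace),
        n_iter=len(trace),
        converged=converged,
    )


def _normalize_rows_max(S: np.ndarray) -> np.ndarray:
    for row in S:
        m = row.max()
        if m > 0:
            row /= m
    return S


def _renormalize(S: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-max rows of S, scale absorbed into C; C @ S is unchanged."""
    scale = S.max(axis=1)
    safe = np.where(scale > 0, scale, 1.0)
    return S / safe[:, None], C * safe[None, :]
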