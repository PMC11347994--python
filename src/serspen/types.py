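"""Core domain types for hyperspectral SERS image analysis.

The data model mirrors how a confocal Raman instrument scans a sectioned
fruit sample: a 2D spatial grid (depth into the pulp x lateral position,
micrometre spacing) where every pixel carries a full Raman spectrum on a
shared wavenumber axis.  Depth index 0 is the pericarp surface and increases
inward.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "ReferenceSpectrum",
    "HyperMap",
    "PipelineConfig",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing Raman-shift grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise DomainError("axis needs at least 2 wavenumbers in a 1-D array")
        if not np.all(np.isfinite(values)):
            raise DomainError("axis values must be finite")
        if np.any(np.diff(values) <= 0):
            raise DomainError("axis values must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> np.ndarray:
        return np.diff(self.values)

    @property
    def is_uniform(self) -> bool:
        d = self.spacing
        return bool(d.max() / d.min() < 1 + 1e-9)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass
class Spectrum:
    """A single Raman spectrum: intensities (a.u.) on a wavenumber axis."""

    axis: WavenumberAxis
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size != len(self.axis):
            raise DomainError(
                f"intensities length {arr.size} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise DomainError("intensities must be finite")
        self.intensities = arr

    def copy_with(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.axis, np.asarray(intensities, dtype=float))


@dataclass
class ReferenceSpectrum:
    """A pesticide library spectrum with its characteristic band positions.

    ``peaks`` is a sequence of ``(center_cm1, half_window_cm1)`` pairs, e.g.
    thiram's characteristic band at 1380 cm^-1 with a +-10 cm^-1 window.
    """

    name: str
    spectrum: Spectrum
    peaks: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        peaks = [(float(c), float(w)) for c, w in self.peaks]
        if not peaks:
            raise DomainError("reference spectrum needs at least one peak")
        lo = float(self.spectrum.axis.values[0])
        hi = float(self.spectrum.axis.values[-1])
        for center, _ in peaks:
            if not (lo <= center <= hi):
                raise DomainError(
                    f"peak center {center} cm^-1 outside axis range [{lo}, {hi}]"
                )
        self.peaks = peaks


@dataclass
class HyperMap:
    """One time-stamped hyperspectral cube.

    ``spectra`` is ``(n_depth * n_lateral, n_channels)``, row-major by
    ``(depth, lateral)``: pixel ``(i, j)`` is row ``i * n_lateral + j``.
    Depth coordinate 0 is the pericarp surface, increasing inward.
    """

    axis: WavenumberAxis
    n_depth: int
    n_lateral: int
    depth_step_um: float
    lateral_step_um: float
    time_h: float
    spectra: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_depth < 1 or self.n_lateral < 1:
            raise DomainError("grid dimensions must be positive")
        if self.depth_step_um <= 0 or self.lateral_step_um <= 0:
            raise DomainError("grid steps must be positive")
        if self.time_h < 0:
            raise DomainError("time_h must be >= 0")
        arr = np.asarray(self.spectra, dtype=float)
        expected = self.n_depth * self.n_lateral
        if arr.shape != (expected, len(self.axis)):
            raise DomainError(
                f"spectra shape {arr.shape} does not match "
                f"({expected}, {len(self.axis)}) from grid and axis"
            )
        if not np.all(np.isfinite(arr)):
            raise DomainError("cube intensities must be finite")
        self.spectra = arr

    @property
    def n_pixels(self) -> int:
        return self.n_depth * self.n_lateral

    @property
    def depth_extent_um(self) -> float:
        return (self.n_depth - 1) * self.depth_step_um

    @property
    def depths_um(self) -> np.ndarray:
        """Depth coordinate of every grid row (surface = 0)."""
        return np.arange(self.n_depth) * self.depth_step_um

    def pixel_depths_um(self) -> np.ndarray:
        """Depth coordinate of every pixel in row-major order."""
        return np.repeat(self.depths_um, self.n_lateral)

    def as_image(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-pixel vector into the (n_depth, n_lateral) grid."""
        values = np.asarray(values)
        if values.size != self.n_pixels:
            raise DomainError("per-pixel vector length does not match grid")
        return values.reshape(self.n_depth, self.n_lateral)

    def pixel_spectrum(self, i_depth: int, j_lateral: int) -> Spectrum:
        return Spectrum(self.axis, self.spectra[i_depth * self.n_lateral + j_lateral])


DEFAULT_COLOR_CODES = {"none": 0, "pesticide_a": 10, "pesticide_b": 20}


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across the analysis stages.

    ``pesticide_threshold``/``suspected_threshold`` implement the published
    decision rule: similarity > 0.8 means pesticide, 0.5-0.8 means suspected
    (possibly partially metabolised) signal, below 0.5 is background.
    """

    pesticide_threshold: float = 0.8
    suspected_threshold: float = 0.5
    color_codes: dict = field(default_factory=lambda: dict(DEFAULT_COLOR_CODES))
    train_fraction: float = 0.7
    n_endmembers: int = 3
    baseline_smoothness: float = 1e5
    baseline_asymmetry: float = 0.01
    baseline_n_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.suspected_threshold < self.pesticide_threshold <= 1):
            raise DomainError(
                "need 0 <= suspected_threshold < pesticide_threshold <= 1"
            )
        if not (0 < self.train_fraction < 1):
            raise DomainError("train_fraction must lie in (0, 1)")
        if self.n_endmembers < 1:
            raise DomainError("n_endmembers must be positive")
        codes = {str(k): int(v) for k, v in self.color_codes.items()}
        if any(v < 0 for v in codes.values()):
            raise DomainError("color codes must be non-negative")
        if len(set(codes.values())) != len(codes):
            raise DomainError("color codes must be distinct")
        self.color_codes = codes
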