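"""Synthetic hyperspectral SERS scenes with known ground truth.

The generator emulates the statistical structure of pesticide-penetration
imaging experiments: each cube is a depth x lateral grid of spectra built
from a linear mixing model

    pixel(z, x) = gain(z, x) * [ sum_k c_k(z, t) * S_k + baseline ] + noise

where ``S_k`` are pesticide fingerprint spectra (sums of Lorentzian bands),
``c_k(z, t)`` is a depth/time concentration field from a reaction-diffusion
model of penetration, ``gain`` is a smooth lognormal field emulating
substrate heterogeneity (the image bias SERS substrates suffer from), and
the noise is additive Gaussian.

Penetration model
-----------------
Concentration obeys a 1-D diffusion equation with enzymatic degradation,

    dc/dt = D d2c/dz2 - k0 * A(t) * R(t) * c,        z in [0, L]

with surface boundary ``c(0, t) = dose * exp(-t / tau_surface)`` (the
sprayed dose drying off) and zero flux at the inner boundary.  The tissue's
enzymatic defense is *induced*: activation ``A(t) = 1 - exp(-t / t_act)``
ramps up after exposure, while the enzyme reserve ``R`` is consumed by the
degradation it performs and slowly resupplied,

    dR/dt = -gamma * A * R * <c>_z + s * (E0 - R),   R(0) = E0.

This minimal model reproduces the experimentally observed three-phase
dynamics: an initial diffusive advance, a retreat while the induced defense
degrades the invading pesticide, and a renewed, deeper advance once the
enzyme reserve is spent.  ``t_act = 0`` disables the induction lag (always
fully active defense).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DomainError
from .sml import SpectraDataset
from .types import HyperMap, ReferenceSpectrum, Spectrum, WavenumberAxis
from .preprocess import build_axis

__all__ = [
    "ComponentConfig",
    "SceneConfig",
    "ConcentrationField",
    "GroundTruth",
    "make_reference_spectrum",
    "simulate_penetration_field",
    "penetration_front_depth",
    "make_gain_field",
    "assemble_hypermap",
    "make_labeled_spectra",
    "default_scene",
]

#: The acquisition schedule of the emulated study, in hours.
STUDY_TIMES_H = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0, 48.0, 72.0, 96.0)


@dataclass(frozen=True)
class ComponentConfig:
    """One pesticide component: its fingerprint bands and transport model.

    ``peaks`` are ``(center_cm1, fwhm_cm1, amplitude)`` triples.  Transport
    parameters: diffusivity ``D`` (um^2/h), maximal degradation rate ``k0``
    (1/h), enzyme capacity ``e0``, consumption rate ``gamma`` (1/h per unit
    mean concentration), resupply rate ``s`` (1/h), induction time ``t_act``
    (h), surface ``dose`` (a.u.) decaying with ``surface_decay_h``.
    """

    name: str
    peaks: Sequence[tuple[float, float, float]]
    dose: float = 1.5
    diffusivity: float = 50.0
    k0: float = 2.0
    e0: float = 1.0
    gamma: float = 3.0
    s: float = 0.02
    t_act: float = 12.0
    surface_decay_h: float = 96.0

    def __post_init__(self) -> None:
        if self.dose < 0 or self.k0 < 0 or self.e0 < 0 or self.gamma < 0 or self.s < 0:
            raise DomainError("rates, doses and enzyme levels must be >= 0")
        if self.diffusivity < 0:
            raise DomainError("diffusivity must be >= 0")
        if self.dose > 0 and self.diffusivity == 0:
            raise DomainError("a dosed component needs positive diffusivity to penetrate")
        if self.t_act < 0 or self.surface_decay_h <= 0:
            raise DomainError("t_act must be >= 0 and surface_decay_h > 0")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic imaging experiment."""

    axis_start_cm1: float = 400.0
    axis_stop_cm1: float = 1800.0
    n_channels: int = 256
    n_depth: int = 40
    n_lateral: int = 20
    depth_step_um: float = 5.0
    lateral_step_um: float = 5.0
    components: tuple[ComponentConfig, ...] = ()
    baseline_amplitude: float = 300.0
    baseline_center_cm1: float = 1100.0
    baseline_width_cm1: float = 600.0
    baseline_slope: float = 0.05
    gain_log_std: float = 0.15
    gain_corr_um: float = 10.0
    noise_sd: float = 20.0
    times_h: tuple[float, ...] = STUDY_TIMES_H
    field_resolution_um: float = 1.0
    band_shape: str = "lorentzian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.gain_log_std < 0 or self.gain_corr_um < 0:
            raise DomainError("noise_sd, gain_log_std and gain_corr_um must be >= 0")
        times = np.asarray(self.times_h, dtype=float)
        if times.size < 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
            raise DomainError("times_h must be non-negative and strictly increasing")
        if self.field_resolution_um <= 0:
            raise DomainError("field_resolution_um must be positive")
        if self.band_shape not in ("lorentzian", "gaussian"):
            raise DomainError("band_shape must be 'lorentzian' or 'gaussian'")

    @property
    def axis(self) -> WavenumberAxis:
        return build_axis(self.axis_start_cm1, self.axis_stop_cm1, self.n_channels)

    @property
    def depth_extent_um(self) -> float:
        return (self.n_depth - 1) * self.depth_step_um

    def baseline(self) -> np.ndarray:
        """Broad fluorescence background evaluated on the scene axis."""
        nu = self.axis.values
        bump = self.baseline_amplitude * np.exp(
            -0.5 * ((nu - self.baseline_center_cm1) / self.baseline_width_cm1) ** 2
        )
        return bump + self.baseline_slope * (nu - nu[0])

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic sub-generator; streams identified by fixed offsets."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, *stream)))


@dataclass
class ConcentrationField:
    """Concentration of one component vs depth (columns) and time (rows)."""

    values: np.ndarray
    depth_um: np.ndarray
    times_h: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.values.shape != (self.times_h.size, self.depth_um.size):
            raise DomainError("field shape does not match depth/time axes")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DomainError("concentrations must be finite and >= 0")

    def at_depths(self, depths_um: np.ndarray) -> np.ndarray:
        """Linear interpolation of every time row onto the given depths."""
        return np.vstack(
            [np.interp(depths_um, self.depth_um, row) for row in self.values]
        )


def _band_profile(nu: np.ndarray, center: float, fwhm: float, shape: str) -> np.ndarray:
    if shape == "lorentzian":
        half = fwhm / 2.0
        return half**2 / ((nu - center) ** 2 + half**2)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((nu - center) / sigma) ** 2)


def make_reference_spectrum(
    peaks: Sequence[tuple[float, float, float]],
    axis: WavenumberAxis,
    shape: str = "lorentzian",
    name: str = "reference",
) -> ReferenceSpectrum:
    """Superpose unit-height bands: intensity = sum_i amp_i * B(nu; c_i, w_i)."""
    if shape not in ("lorentzian", "gaussian"):
        raise DomainError("shape must be 'lorentzian' or 'gaussian'")
    peaks = [(float(c), float(w), float(a)) for c, w, a in peaks]
    if not peaks:
        raise DomainError("need at least one band")
    nu = axis.values
    lo, hi = float(nu[0]), float(nu[-1])
    y = np.zeros_like(nu)
    for center, fwhm, amp in peaks:
        if not (lo <= center <= hi):
            raise DomainError(f"band center {center} outside axis range [{lo}, {hi}]")
        if fwhm <= 0:
            raise DomainError("band FWHM must be positive")
        y += amp * _band_profile(nu, center, fwhm, shape)
    return ReferenceSpectrum(
        name=name,
        spectrum=Spectrum(axis, y),
        peaks=[(c, w) for c, w, _ in peaks],
    )


def simulate_penetration_field(
    cfg: SceneConfig,
    component_index: int,
    initial: np.ndarray | None = None,
) -> ConcentrationField:
    """Solve the penetration reaction-diffusion model for one component.

    Explicit finite differences on a uniform depth grid at
    ``cfg.field_resolution_um`` spacing, sub-stepped to keep
    ``D*dt/dz^2 <= 0.4``.  ``initial`` optionally sets c(z, 0) (same grid);
    with a zero surface dose the surface boundary is reflecting, so a free
    decaying pulse conserves the expected mass budget.
    """
    comp = cfg.components[component_index]
    L = cfg.depth_extent_um
    nz = int(round(L / cfg.field_resolution_um)) + 1
    z = np.linspace(0.0, L, nz)
    dz = z[1] - z[0]
    D, k0, E0 = comp.diffusivity, comp.k0, comp.e0
    gamma, s, t_act = comp.gamma, comp.s, comp.t_act
    dose, tau = comp.dose, comp.surface_decay_h

    if initial is None:
        c = np.zeros(nz)
    else:
        c = np.asarray(initial, dtype=float).copy()
        if c.shape != z.shape:
            raise DomainError(f"initial condition must have {nz} points on the field grid")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise DomainError("initial concentrations must be finite and >= 0")

    # explicit diffusion stability bound; reaction terms use exact
    # exponential updates (operator splitting), so they do not limit dt
    dt_max = min(0.4 * dz * dz / D, 0.05) if D > 0 else 0.05

    dirichlet = dose > 0
    if dirichlet:
        c[0] = dose
    R = E0
    t = 0.0
    times = np.asarray(cfg.times_h, dtype=float)
    rows = []
    for t_target in times:
        while t < t_target - 1e-12:
            dt = min(dt_max, t_target - t)
            A = 1.0 if t_act == 0 else 1.0 - np.exp(-(t + 0.5 * dt) / t_act)
            lap = np.zeros(nz)
            lap[1:-1] = (c[2:] - 2.0 * c[1:-1] + c[:-2]) / dz**2
            lap[-1] = 2.0 * (c[-2] - c[-1]) / dz**2
            if not dirichlet:
                lap[0] = 2.0 * (c[1] - c[0]) / dz**2
            cbar = float(np.trapezoid(c, z) / L)
            c_new = (c + dt * D * lap) * np.exp(-k0 * A * R * dt)
            if dirichlet:
                c_new[0] = dose * np.exp(-(t + dt) / tau)
            # dR/dt = -(a + s) R + s E0 with a = gamma * A * <c>: linear, exact step
            a = gamma * A * cbar
            decay = np.exp(-(a + s) * dt)
            R_inf = s * E0 / (a + s) if (a + s) > 0 else R
            R = max(R_inf + (R - R_inf) * decay, 0.0)
            c = np.maximum(c_new, 0.0)
            t += dt
        rows.append(c.copy())
    return ConcentrationField(values=np.vstack(rows), depth_um=z, times_h=times)


def penetration_front_depth(field: ConcentrationField, fraction: float = 0.05) -> np.ndarray:
    """Deepest depth with concentration above ``fraction`` of the surface value,
    per time point (0 where nothing exceeds the threshold)."""
    if not (0 < fraction < 1):
        raise DomainError("fraction must lie in (0, 1)")
    fronts = np.zeros(field.times_h.size)
    for i, row in enumerate(field.values):
        thr = fraction * row[0]
        idx = np.nonzero(row > thr)[0] if thr > 0 else np.array([], dtype=int)
        fronts[i] = field.depth_um[idx[-1]] if idx.size else 0.0
    return fronts


def make_gain_field(cfg: SceneConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Multiplicative substrate-heterogeneity field, shape (n_depth, n_lateral).

    Lognormal marginals with the configured log-std, spatially correlated at
    ``gain_corr_um`` via Gaussian smoothing of the underlying normal field
    (re-standardised so the log-std survives the smoothing), and unit mean
    in expectation.
    """
    if rng is None:
        rng = cfg.rng(1)
    shape = (cfg.n_depth, cfg.n_lateral)
    if cfg.gain_log_std == 0:
        return np.ones(shape)
    zfield = rng.standard_normal(shape)
    if cfg.gain_corr_um > 0:
        sigma_px = (cfg.gain_corr_um / cfg.depth_step_um, cfg.gain_corr_um / cfg.lateral_step_um)
        zfield = ndimage.gaussian_filter(zfield, sigma=sigma_px, mode="nearest")
        sd = zfield.std()
        if sd > 0:
            zfield = zfield / sd
    log_sd = cfg.gain_log_std
    return np.exp(log_sd * zfield - 0.5 * log_sd**2)


@dataclass
class GroundTruth:
    """Everything the generator knew when it built a cube."""

    concentrations: np.ndarray  # (n_pixels, n_components), before gain
    endmembers: np.ndarray  # (n_components, n_channels)
    component_names: tuple[str, ...]
    baseline: np.ndarray  # (n_channels,)
    gain: np.ndarray  # (n_depth, n_lateral)
    clean: np.ndarray  # (n_pixels, n_channels), noise-free cube
    noise_sd: float


def assemble_hypermap(
    cfg: SceneConfig, time_h: float
) -> tuple[HyperMap, GroundTruth]:
    """Build the cube for one acquisition time, plus its ground truth.

    Fully determined by ``cfg.seed``: the gain field uses one fixed stream
    and the noise a per-time-point stream, so cubes at different times are
    independently reproducible.
    """
    times = np.asarray(cfg.times_h, dtype=float)
    matches = np.nonzero(np.isclose(times, time_h))[0]
    if matches.size == 0:
        raise DomainError(f"time {time_h} h is not one of the scene's time points")
    t_idx = int(matches[0])
    if not cfg.components:
        raise DomainError("scene has no components")

    axis = cfg.axis
    refs = [
        make_reference_spectrum(comp.peaks, axis, cfg.band_shape, comp.name)
        for comp in cfg.components
    ]
    S = np.vstack([r.spectrum.intensities for r in refs])
    depths = np.arange(cfg.n_depth) * cfg.depth_step_um
    conc_depth = np.empty((cfg.n_depth, len(cfg.components)))
    for k in range(len(cfg.components)):
        fld = simulate_penetration_field(cfg, k)
        conc_depth[:, k] = np.interp(depths, fld.depth_um, fld.values[t_idx])
    C = np.repeat(conc_depth, cfg.n_lateral, axis=0)  # (n_pixels, p)

    baseline = cfg.baseline()
    gain = make_gain_field(cfg, cfg.rng(1))
    gain_px = gain.reshape(-1, 1)
    clean = gain_px * (C @ S + baseline)
    noise_rng = cfg.rng(2, t_idx)
    noisy = clean + noise_rng.normal(0.0, cfg.noise_sd, clean.shape) if cfg.noise_sd > 0 else clean.copy()

    cube = HyperMap(
        axis=axis,
        n_depth=cfg.n_depth,
        n_lateral=cfg.n_lateral,
        depth_step_um=cfg.depth_step_um,
        lateral_step_um=cfg.lateral_step_um,
        time_h=float(times[t_idx]),
        spectra=noisy,
        metadata={"scene_seed": cfg.seed, "components": [c.name for c in cfg.components]},
    )
    truth = GroundTruth(
        concentrations=C,
        endmembers=S,
        component_names=tuple(c.name for c in cfg.components),
        baseline=baseline,
        gain=gain,
        clean=clean,
        noise_sd=cfg.noise_sd,
    )
    return cube, truth


#: log-uniform surface-dose range used when drawing labeled training spectra
LABELED_DOSE_RANGE = (0.1, 2.0)


def make_labeled_spectra(
    cfg: SceneConfig,
    n_per_class: int,
    classes: Sequence[str] | None = None,
    seed: int | None = None,
) -> SpectraDataset:
    """Labeled single spectra for classifier training.

    Pesticide classes: ``dose * fingerprint + baseline + noise`` with dose
    log-uniform in ``LABELED_DOSE_RANGE``; the ``background`` class is
    baseline + noise only.  Rows are shuffled deterministically.
    """
    if n_per_class < 1:
        raise DomainError("n_per_class must be >= 1")
    known = {c.name: c for c in cfg.components}
    if classes is None:
        classes = [*known, "background"]
    for cls in classes:
        if cls != "background" and cls not in known:
            raise DomainError(f"unknown class name: {cls!r}")
    rng = cfg.rng(3) if seed is None else np.random.default_rng(seed)
    axis = cfg.axis
    baseline = cfg.baseline()
    n_total = n_per_class * len(classes)
    X = np.empty((n_total, len(axis)))
    labels = []
    row = 0
    lo, hi = LABELED_DOSE_RANGE
    for cls in classes:
        if cls == "background":
            block = np.tile(baseline, (n_per_class, 1))
        else:
            ref = make_reference_spectrum(known[cls].peaks, axis, cfg.band_shape, cls)
            doses = np.exp(rng.uniform(np.log(lo), np.log(hi), n_per_class))
            block = doses[:, None] * ref.spectrum.intensities + baseline
        X[row : row + n_per_class] = block
        labels.extend([cls] * n_per_class)
        row += n_per_class
    if cfg.noise_sd > 0:
        X += rng.normal(0.0, cfg.noise_sd, X.shape)
    order = rng.permutation(n_total)
    return SpectraDataset(
        X=X[order],
        labels=[labels[i] for i in order],
        provenance="synthetic",
    )


# band positions loosely modeled on published SERS fingerprints of the two
# pesticides contrasted in the study (a.u. amplitudes; FWHM 14 cm^-1)
_CHLORPYRIFOS_PEAKS = (
    (632.0, 14.0, 800.0),
    (685.0, 14.0, 1000.0),
    (980.0, 14.0, 550.0),
    (1096.0, 14.0, 450.0),
    (1240.0, 14.0, 350.0),
    (1575.0, 14.0, 300.0),
)
_ACETAMIPRID_PEAKS = (
    (730.0, 14.0, 600.0),
    (1109.0, 14.0, 1000.0),
    (1366.0, 14.0, 700.0),
    (1581.0, 14.0, 500.0),
)


def default_scene(seed: int = 0, **overrides) -> SceneConfig:
    """The demo scene: a non-systemic and a systemic pesticide on apple pulp.

    The non-systemic component (chlorpyrifos-like) carries the full
    induced-defense dynamics; the systemic one (acetamiprid-like) penetrates
    deeper with weaker degradation and a persistent surface supply.
    """
    components = (
        ComponentConfig(name="chlorpyrifos", peaks=_CHLORPYRIFOS_PEAKS),
        ComponentConfig(
            name="acetamiprid",
            peaks=_ACETAMIPRID_PEAKS,
            dose=1.0,
            diffusivity=80.0,
            k0=0.5,
            t_act=12.0,
            surface_decay_h=200.0,
        ),
    )
    return replace(SceneConfig(components=components, seed=seed), **overrides)
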