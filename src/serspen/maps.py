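"""Similarity maps, threshold classification, and mixed-pesticide overlap maps.

Per-pixel similarity of the (baseline-corrected, l2-normalized) spectrum to
a reference yields the heat map; the published decision rule then labels
each pixel: similarity strictly above 0.8 is a pesticide, between 0.5 and
0.8 inclusive a suspected (possibly partially metabolised) signal, below
0.5 background.

For pesticide mixtures, presence is decided independently against each
reference from Euclidean-distance similarity, and the categorical map is
encoded additively: nothing = 0, component A = 10, component B = 20,
overlap = 30 (codes configurable).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .preprocess import baseline_correct_matrix, normalize_rows
from .types import HyperMap, PipelineConfig, ReferenceSpectrum, Spectrum

__all__ = [
    "SimilarityMap",
    "LabelMap",
    "pearson_similarity",
    "euclidean_distance",
    "ed_to_similarity",
    "similarity_map",
    "classify_similarity",
    "mixed_overlap_map",
    "CATEGORIES",
]

CATEGORIES = ("background", "suspected", "pesticide")


@dataclass
class SimilarityMap:
    values: np.ndarray  # (n_depth, n_lateral)
    metric: str
    reference_name: str
    time_h: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or not np.all(np.isfinite(self.values)):
            raise DomainError("similarity map must be a finite 2-D matrix")


@dataclass
class LabelMap:
    labels: np.ndarray  # (n_depth, n_lateral) of category strings
    categories: tuple[str, ...]
    color_values: np.ndarray  # same shape, integer codes

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.color_values = np.asarray(self.color_values, dtype=int)
        if self.labels.shape != self.color_values.shape:
            raise DomainError("labels and color values must share a shape")


def pearson_similarity(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> float:
    """Pearson correlation of two intensity vectors."""
    va = a.intensities if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    vb = b.intensities if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise DomainError("spectra must have equal length")
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        raise DomainError("Pearson similarity undefined for a constant spectrum")
    return float(np.corrcoef(va, vb)[0, 1])


def euclidean_distance(
    a: Spectrum | np.ndarray, b: Spectrum | np.ndarray, normalize: bool = True
) -> float:
    """Euclidean distance, optionally after l2-normalizing both spectra."""
    va = a.intensities if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    vb = b.intensities if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise DomainError("spectra must have equal length")
    if normalize:
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise DomainError("cannot l2-normalize a zero spectrum")
        va, vb = va / na, vb / nb
    return float(np.linalg.norm(va - vb))


def ed_to_similarity(d: float) -> float:
    """Map a distance to a similarity in (0, 1]: ``1 / (1 + d)``."""
    if d < 0:
        raise DomainError("distance must be >= 0")
    return 1.0 / (1.0 + d)


def _prepare_pixels(cube: HyperMap, cfg: PipelineConfig, correct_baseline: bool) -> np.ndarray:
    X = cube.spectra
    if correct_baseline:
        X = baseline_correct_matrix(
            X, cfg.baseline_smoothness, cfg.baseline_asymmetry, cfg.baseline_n_iter
        )
    return normalize_rows(X)


def similarity_map(
    cube: HyperMap,
    ref: ReferenceSpectrum,
    metric: str = "pearson",
    cfg: PipelineConfig | None = None,
    correct_baseline: bool = True,
) -> SimilarityMap:
    """Per-pixel similarity of the cube to a reference spectrum.

    Pixels are baseline-corrected (AsLS, config defaults) and l2-normalized
    before the metric; the reference is l2-normalized.  The cube and
    reference must share a wavenumber axis — resample first otherwise.
    """
    if metric not in ("pearson", "ed"):
        raise DomainError("metric must be 'pearson' or 'ed'")
    if ref.spectrum.axis != cube.axis:
        raise DomainError(
            "cube and reference are on different wavenumber axes; "
            "resample the reference with resample_spectrum first"
        )
    cfg = cfg or PipelineConfig()
    X = _prepare_pixels(cube, cfg, correct_baseline)
    r = ref.spectrum.intensities
    rn = np.linalg.norm(r)
    if rn == 0:
        raise DomainError("reference spectrum is all zero")
    r = r / rn
    if metric == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        rc = r - r.mean()
        denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(rc)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (Xc @ rc) / denom
        vals = np.where(denom > 0, vals, 0.0)
        vals = np.clip(vals, -1.0, 1.0)
    else:
        d = np.linalg.norm(X - r, axis=1)
        vals = 1.0 / (1.0 + d)
    return SimilarityMap(
        values=cube.as_image(vals), metric=metric, reference_name=ref.name, time_h=cube.time_h
    )


def classify_similarity(sim: SimilarityMap, cfg: PipelineConfig | None = None) -> LabelMap:
    """Threshold a similarity map into background / suspected / pesticide.

    Strictly-greater rule at the upper cutoff: a value of exactly 0.8 is
    'suspected', not 'pesticide'; below 0.5 (strict) is background.
    """
    cfg = cfg or PipelineConfig()
    v = sim.values
    labels = np.full(v.shape, "background", dtype=object)
    labels[(v >= cfg.suspected_threshold) & (v <= cfg.pesticide_threshold)] = "suspected"
    labels[v > cfg.pesticide_threshold] = "pesticide"
    code_of = {"background": 0, "suspected": 1, "pesticide": 2}
    colors = np.vectorize(code_of.__getitem__)(labels).astype(int)
    return LabelMap(labels=labels, categories=CATEGORIES, color_values=colors)


def mixed_overlap_map(
    cube: HyperMap,
    ref_a: ReferenceSpectrum,
    ref_b: ReferenceSpectrum,
    cfg: PipelineConfig | None = None,
    correct_baseline: bool = True,
) -> LabelMap:
    """Additively coded co-localization map for a two-pesticide mixture.

    Each pixel is tested for each pesticide independently (ED similarity
    above the pesticide threshold); the color value is the sum of the
    per-pesticide codes, so with defaults: none 0, A-only 10, B-only 20,
    overlap 30.
    """
    cfg = cfg or PipelineConfig()
    if ref_a.name == ref_b.name or np.array_equal(
        ref_a.spectrum.intensities, ref_b.spectrum.intensities
    ):
        raise DomainError("mixed overlap map needs two distinct references")
    sim_a = similarity_map(cube, ref_a, "ed", cfg, correct_baseline)
    sim_b = similarity_map(cube, ref_b, "ed", cfg, correct_baseline)
    present_a = sim_a.values > cfg.pesticide_threshold
    present_b = sim_b.values > cfg.pesticide_threshold
    code_a = cfg.color_codes.get("pesticide_a", 10)
    code_b = cfg.color_codes.get("pesticide_b", 20)
    colors = code_a * present_a.astype(int) + code_b * present_b.astype(int)
    labels = np.full(colors.shape, "none", dtype=object)
    labels[present_a & ~present_b] = ref_a.name
    labels[present_b & ~present_a] = ref_b.name
    labels[present_a & present_b] = "both"
    return LabelMap(
        labels=labels,
        categories=("none", ref_a.name, ref_b.name, "both"),
        color_values=colors,
    )
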