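"""Reference workflows exercising the full analysis chain at study scale.

These functions wire the stages together exactly as the analysis intends
them to be used, so that recovery and classification performance can be
measured end to end against generator ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .mcr import run_mcr_als
from .preprocess import baseline_correct_matrix
from .sml import (
    CLASSIFIER_FAMILIES,
    curate_training_set,
    evaluate,
    split_dataset,
    train_classifier,
)
from .synthetic import (
    SceneConfig,
    assemble_hypermap,
    default_scene,
    make_labeled_spectra,
    make_reference_spectrum,
)
from .types import PipelineConfig
from .unmix import match_endmembers, run_vca

__all__ = [
    "ClassificationBenchmark",
    "curated_classification_aucs",
    "mcr_recovery_correlation",
    "noise_sd_for_snr",
]


@dataclass
class ClassificationBenchmark:
    """AUC per family and class, plus the split sizes behind them."""

    aucs: dict  # family -> {class -> held-out AUC}
    n_train: int
    n_test: int

    def min_auc(self) -> float:
        return min(v for d in self.aucs.values() for v in d.values())


def noise_sd_for_snr(scene: SceneConfig, time_h: float, snr_db: float) -> float:
    """Additive-noise sigma that realizes the target SNR on a scene's cube."""
    clean_scene = replace(scene, noise_sd=0.0)
    _, truth = assemble_hypermap(clean_scene, time_h)
    return float(np.sqrt(np.mean(truth.clean**2) / 10 ** (snr_db / 10.0)))


def curated_classification_aucs(
    n_per_class: int = 5000,
    seed: int = 1,
    families: Sequence[str] = CLASSIFIER_FAMILIES,
    train_fraction: float = 0.7,
) -> ClassificationBenchmark:
    """Held-out one-vs-rest AUC per classifier family and class.

    Full curation pipeline on the default two-pesticide scene: generate
    labeled spectra, baseline-correct, extract and match VCA endmembers,
    curate by K-means centroid similarity, stratified 70/30 split, train
    each family, evaluate on the held-out 30%.
    """
    scene = default_scene(seed=seed)
    pipe = PipelineConfig(train_fraction=train_fraction, seed=seed)
    ds = make_labeled_spectra(scene, n_per_class, seed=seed)
    Xc = baseline_correct_matrix(ds.X)
    refs = [
        make_reference_spectrum(c.peaks, scene.axis, scene.band_shape, c.name)
        for c in scene.components
    ]
    E = match_endmembers(run_vca(Xc, len(refs) + 1, seed=seed), refs)
    curated = curate_training_set(Xc, E, pipe, seed=seed)
    train, test = split_dataset(curated, train_fraction, seed=seed)
    out: dict[str, dict[str, float]] = {}
    for family in families:
        model = train_classifier(train, family, seed=seed)
        report = evaluate(model, test)
        out[family] = dict(report.auc)
    return ClassificationBenchmark(aucs=out, n_train=len(train), n_test=len(test))


def mcr_recovery_correlation(
    scene: SceneConfig,
    time_h: float = 24.0,
    snr_db: float = 25.0,
    seed: int = 0,
) -> dict[str, float]:
    """Pearson r between true and MCR-ALS-estimated per-pixel concentration
    of each pesticide component, at the stated cube SNR."""
    sd = noise_sd_for_snr(scene, time_h, snr_db)
    noisy_scene = replace(scene, noise_sd=sd)
    cube, truth = assemble_hypermap(noisy_scene, time_h)
    Xc = baseline_correct_matrix(cube.spectra)
    refs = [
        make_reference_spectrum(c.peaks, scene.axis, scene.band_shape, c.name)
        for c in scene.components
    ]
    E = match_endmembers(run_vca(Xc, len(refs) + 1, seed=seed), refs)
    res = run_mcr_als(Xc, E)
    out = {}
    for k, name in enumerate(truth.component_names):
        if res.S.names is None or name not in res.S.names:
            out[name] = float("nan")
            continue
        col = res.S.names.index(name)
        out[name] = float(np.corrcoef(truth.concentrations[:, k], res.C.C[:, col])[0, 1])
    return out
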