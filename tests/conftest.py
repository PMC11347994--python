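import numpy as np
import pytest

from serspen import build_axis, make_reference_spectrum
from serspen.synthetic import ComponentConfig, SceneConfig


@pytest.fixture(scope="session")
def axis128():
    return build_axis(400.0, 1800.0, 128)


@pytest.fixture(scope="session")
def three_refs(axis128):
    """Three spectrally distinct pesticide fingerprints on a shared axis."""
    bands = [
        [(600.0, 14.0, 1000.0), (900.0, 14.0, 600.0)],
        [(800.0, 14.0, 1000.0), (1050.0, 14.0, 600.0)],
        [(1000.0, 14.0, 1000.0), (1200.0, 14.0, 600.0)],
    ]
    return [
        make_reference_spectrum(b, axis128, name=f"pesticide_{i}")
        for i, b in enumerate(bands)
    ]


@pytest.fixture(scope="session")
def pure_pixel_cube(three_refs):
    """Noiseless 32x32 mixing of three fingerprints with pure pixels.

    Mixtures are convex combinations (abundances sum to one) with one
    guaranteed pure pixel per component, so the maximum-volume pixel triple
    is exactly the pure-pixel set; returns (X, S_true, C_true).
    """
    rng = np.random.default_rng(11)
    S = np.vstack([r.spectrum.intensities for r in three_refs])
    n = 32 * 32
    C = rng.dirichlet([0.6, 0.6, 0.6], size=n)
    C[100] = [1.0, 0.0, 0.0]
    C[500] = [0.0, 1.0, 0.0]
    C[900] = [0.0, 0.0, 1.0]
    return C @ S, S, C


@pytest.fixture(scope="session")
def single_component_scene():
    """A single-pesticide scene (one cube per study time) used for recovery."""
    comp = ComponentConfig(
        name="chlorpyrifos",
        peaks=((632.0, 14.0, 800.0), (685.0, 14.0, 1000.0), (980.0, 14.0, 550.0),
               (1096.0, 14.0, 450.0), (1240.0, 14.0, 350.0), (1575.0, 14.0, 300.0)),
    )
    return SceneConfig(components=(comp,), n_depth=32, n_lateral=16, noise_sd=0.0, seed=7)
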