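"""Synthetic scene generator: fingerprints, penetration PDE, gain field,
cube assembly and labeled spectra."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from serspen import (
    assemble_hypermap,
    build_axis,
    default_scene,
    make_gain_field,
    make_labeled_spectra,
    make_reference_spectrum,
    penetration_front_depth,
    simulate_penetration_field,
)
from serspen.errors import DomainError
from serspen.synthetic import ComponentConfig, SceneConfig


class TestReferenceSpectrum:
    def test_thiram_characteristic_band_at_1380(self, axis128):
        """A single band at thiram's characteristic shift peaks exactly there."""
        axis = build_axis(400, 1800, 701)
        ref = make_reference_spectrum([(1380.0, 14.0, 1000.0)], axis, name="thiram")
        argmax_nu = axis.values[np.argmax(ref.spectrum.intensities)]
        nearest = axis.values[np.argmin(np.abs(axis.values - 1380.0))]
        assert argmax_nu == nearest
        assert ref.peaks == [(1380.0, 14.0)]

    def test_zero_amplitude_gives_zero_spectrum(self, axis128):
        ref = make_reference_spectrum([(1000.0, 14.0, 0.0)], axis128)
        assert np.all(ref.spectrum.intensities == 0)

    def test_two_lorentzians_match_closed_form(self):
        axis = build_axis(400, 1800, 1401)
        c1, c2, w, a1, a2 = 700.0, 1300.0, 12.0, 1000.0, 500.0
        ref = make_reference_spectrum([(c1, w, a1), (c2, w, a2)], axis, "lorentzian")

        def lor(nu, c, a):
            return a * (w / 2) ** 2 / ((nu - c) ** 2 + (w / 2) ** 2)

        expected = lor(axis.values, c1, a1) + lor(axis.values, c2, a2)
        assert np.max(np.abs(ref.spectrum.intensities - expected)) < 1e-9

    def test_center_outside_axis_rejected(self, axis128):
        with pytest.raises(DomainError):
            make_reference_spectrum([(2000.0, 14.0, 1.0)], axis128)


def _pulse_scene(**comp_kw):
    comp = ComponentConfig(name="x", peaks=((1000.0, 14.0, 1.0),), **comp_kw)
    return SceneConfig(
        components=(comp,), n_depth=21, n_lateral=4, times_h=(0.5, 1, 2, 4),
        field_resolution_um=1.0,
    )


class TestPenetrationField:
    def test_free_diffusion_conserves_mass(self):
        """No degradation, no source: trapezoid mass is constant to 0.1%."""
        cfg = _pulse_scene(dose=0.0, diffusivity=50.0, k0=0.0, gamma=0.0, s=0.0)
        z = np.linspace(0, cfg.depth_extent_um, 101)
        c0 = np.exp(-0.5 * ((z - 50.0) / 10.0) ** 2)
        fld = simulate_penetration_field(cfg, 0, initial=c0)
        m0 = np.trapezoid(c0, z)
        masses = np.trapezoid(fld.values, fld.depth_um, axis=1)
        assert np.all(np.abs(masses / m0 - 1) < 1e-3)

    def test_pure_degradation_matches_ode_oracle(self):
        """D=0: every depth decays by the same factor; oracle = stiff ODE solve."""
        cfg = _pulse_scene(dose=0.0, diffusivity=0.0, k0=2.0, e0=1.0,
                           gamma=3.0, s=0.02, t_act=12.0)
        z = np.linspace(0, cfg.depth_extent_um, 101)
        c0 = np.exp(-0.5 * ((z - 50.0) / 10.0) ** 2)
        fld = simulate_penetration_field(cfg, 0, initial=c0)
        cbar0 = np.trapezoid(c0, z) / cfg.depth_extent_um

        def rhs(t, y):
            f, r = y
            a = 1.0 - np.exp(-t / 12.0)
            return [-2.0 * a * r * f, -3.0 * a * r * cbar0 * f + 0.02 * (1.0 - r)]

        sol = solve_ivp(rhs, (0, 4), [1.0, 1.0], t_eval=cfg.times_h,
                        rtol=1e-10, atol=1e-12)
        for i in range(len(cfg.times_h)):
            expected = c0 * sol.y[0][i]
            rel = np.max(np.abs(fld.values[i] - expected)) / np.max(expected)
            assert rel < 0.01

    def test_default_front_rises_dips_and_rises_again(self):
        """The default scene reproduces the three-phase weakening dynamics
        over the 2-96 h schedule: advance, retreat, renewed advance."""
        scene = default_scene(seed=0)
        fld = simulate_penetration_field(scene, 0)
        front = penetration_front_depth(fld)
        signs = [int(np.sign(d)) for d in np.diff(front) if d != 0]
        compressed = []
        for sgn in signs:
            if not compressed or compressed[-1] != sgn:
                compressed.append(sgn)
        assert compressed[:3] == [1, -1, 1]

    def test_negative_parameters_rejected(self):
        with pytest.raises(DomainError):
            ComponentConfig(name="x", peaks=((1000.0, 14.0, 1.0),), k0=-1.0)

    def test_concentrations_nonnegative_and_finite(self):
        fld = simulate_penetration_field(default_scene(seed=3), 1)
        assert np.all(np.isfinite(fld.values)) and np.all(fld.values >= 0)


class TestGainField:
    def test_zero_log_std_gives_ones(self):
        cfg = SceneConfig(gain_log_std=0.0)
        assert np.all(make_gain_field(cfg) == 1.0)

    def test_log_std_recovered_over_seeds(self):
        sds = []
        for seed in range(5):
            cfg = SceneConfig(n_depth=64, n_lateral=64, depth_step_um=5.0,
                              lateral_step_um=5.0, gain_log_std=0.3, seed=seed)
            g = make_gain_field(cfg)
            assert abs(g.mean() - 1.0) < 0.02
            sds.append(np.log(g).std())
        assert abs(np.mean(sds) - 0.3) / 0.3 < 0.15

    def test_same_seed_identical(self):
        cfg = SceneConfig(n_depth=16, n_lateral=16, gain_log_std=0.2, seed=9)
        assert np.array_equal(make_gain_field(cfg), make_gain_field(cfg))


class TestAssembleHypermap:
    def test_exact_low_rank_when_clean(self):
        scene = default_scene(seed=2, noise_sd=0.0, gain_log_std=0.0,
                              baseline_amplitude=0.0, baseline_slope=0.0,
                              n_depth=16, n_lateral=8)
        cube, _ = assemble_hypermap(scene, 24.0)
        sv = np.linalg.svd(cube.spectra, compute_uv=False)
        assert sv[2] < 1e-9 * sv[0]

    def test_same_seed_bit_identical(self):
        scene = default_scene(seed=5, n_depth=12, n_lateral=6)
        a, _ = assemble_hypermap(scene, 8.0)
        b, _ = assemble_hypermap(scene, 8.0)
        assert np.array_equal(a.spectra, b.spectra)

    def test_realized_snr_matches_target(self):
        """Noise sd derived for a 20 dB target gives a realized SNR within 1 dB."""
        scene0 = default_scene(seed=4, noise_sd=0.0, n_depth=16, n_lateral=8)
        _, truth0 = assemble_hypermap(scene0, 24.0)
        target_db = 20.0
        sd = float(np.sqrt(np.mean(truth0.clean**2) / 10 ** (target_db / 10)))
        scene = default_scene(seed=4, noise_sd=sd, n_depth=16, n_lateral=8)
        cube, truth = assemble_hypermap(scene, 24.0)
        noise = cube.spectra - truth.clean
        realized = 10 * np.log10(np.mean(truth.clean**2) / np.mean(noise**2))
        assert abs(realized - target_db) < 1.0

    def test_unknown_time_rejected(self):
        with pytest.raises(DomainError):
            assemble_hypermap(default_scene(seed=0), 5.0)


class TestLabeledSpectra:
    def test_counts_per_class(self):
        ds = make_labeled_spectra(default_scene(seed=1), 100)
        assert len(ds) == 300
        for cls in ("chlorpyrifos", "acetamiprid", "background"):
            assert ds.labels.count(cls) == 100

    def test_zero_noise_same_class_structure(self):
        scene = default_scene(seed=1, noise_sd=0.0)
        ds = make_labeled_spectra(scene, 20)
        bg = ds.X[[i for i, l in enumerate(ds.labels) if l == "background"]]
        assert np.all(bg == bg[0])  # background has no dose jitter

    def test_within_class_correlation_exceeds_between(self):
        ds = make_labeled_spectra(default_scene(seed=1), 60)
        corr = np.corrcoef(ds.X)
        labels = np.asarray(ds.labels)
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(ds), dtype=bool)
        within = corr[same & off_diag].mean()
        between = corr[~same].mean()
        assert within > between

    def test_unknown_class_rejected(self):
        with pytest.raises(DomainError):
            make_labeled_spectra(default_scene(seed=1), 5, classes=["atrazine"])
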