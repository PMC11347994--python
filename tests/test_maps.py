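"""Similarity metrics, threshold classification and overlap maps."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from serspen import (
    HyperMap,
    PipelineConfig,
    SimilarityMap,
    classify_similarity,
    default_scene,
    ed_to_similarity,
    euclidean_distance,
    mixed_overlap_map,
    pearson_similarity,
    similarity_map,
)
from serspen.errors import DomainError


class TestPearson:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 5.0, 2.0])
        assert pearson_similarity(v, v) == pytest.approx(1.0)

    def test_negated_affine_is_minus_one(self):
        v = np.array([1.0, 5.0, 2.0])
        assert pearson_similarity(v, -v + 10.0) == pytest.approx(-1.0)

    def test_affine_relation_is_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson_similarity(a, 2 * a) == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(DomainError):
            pearson_similarity(np.ones(4), np.arange(4.0))


class TestEuclidean:
    def test_identical_zero_distance_unit_similarity(self):
        v = np.array([1.0, 2.0])
        assert euclidean_distance(v, v) == 0.0
        assert ed_to_similarity(0.0) == 1.0

    def test_orthonormal_closed_form(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        d = euclidean_distance(a, b, normalize=True)
        assert d == pytest.approx(np.sqrt(2))
        assert ed_to_similarity(d) == pytest.approx(1 / (1 + np.sqrt(2)))

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        d = euclidean_distance(a, b, normalize=False)
        assert d == pytest.approx(np.sqrt(np.sum((a - b) ** 2)), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            euclidean_distance(np.ones(3), np.ones(4))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0.1, 1, 8), rng.uniform(0.1, 1, 8)
        perm = rng.permutation(8)
        s_ab = ed_to_similarity(euclidean_distance(a, b))
        s_ba = ed_to_similarity(euclidean_distance(b, a))
        s_perm = ed_to_similarity(euclidean_distance(a[perm], b[perm]))
        assert s_ab == pytest.approx(s_ba, abs=1e-12)
        assert s_ab == pytest.approx(s_perm, abs=1e-12)


def _cube_of(spectra, axis, n_depth, n_lateral):
    return HyperMap(
        axis=axis, n_depth=n_depth, n_lateral=n_lateral,
        depth_step_um=5.0, lateral_step_um=5.0, time_h=2.0, spectra=spectra,
    )


class TestSimilarityMap:
    def test_pixels_equal_to_reference_score_high(self, three_refs, axis128):
        ref = three_refs[0]
        rng = np.random.default_rng(0)
        X = np.tile(ref.spectrum.intensities, (16, 1))
        X = X + rng.normal(0, 1e-6, X.shape)
        cube = _cube_of(X, axis128, 4, 4)
        sim = similarity_map(cube, ref, "pearson", correct_baseline=False)
        assert np.all(sim.values > 0.999)

    def test_background_cube_scores_low(self, three_refs):
        scene = default_scene(seed=6, n_depth=6, n_lateral=6)
        nu = scene.axis.values
        rng = np.random.default_rng(6)
        X = scene.baseline() + rng.normal(0, scene.noise_sd, (36, len(nu)))
        cube = _cube_of(X, scene.axis, 6, 6)
        from serspen import make_reference_spectrum
        ref = make_reference_spectrum(scene.components[0].peaks, scene.axis,
                                      name="chlorpyrifos")
        sim = similarity_map(cube, ref, "pearson")
        assert sim.values.mean() < 0.3

    def test_seeded_pixel_is_argmax(self, three_refs, axis128):
        scene = default_scene(seed=8, n_depth=5, n_lateral=5)
        rng = np.random.default_rng(8)
        ref_on_axis = three_refs[0]
        X = 300.0 * np.exp(-0.5 * ((axis128.values - 1100) / 600) ** 2)
        X = np.tile(X, (25, 1)) + rng.normal(0, 10.0, (25, 128))
        X[13] += 800.0 * ref_on_axis.spectrum.intensities / ref_on_axis.spectrum.intensities.max()
        cube = _cube_of(X, axis128, 5, 5)
        sim = similarity_map(cube, ref_on_axis, "pearson")
        assert np.argmax(sim.values) == 13

    def test_axis_mismatch_instructs_resample(self, three_refs):
        from serspen import build_axis
        cube = _cube_of(np.ones((4, 64)), build_axis(400, 1800, 64), 2, 2)
        with pytest.raises(DomainError, match="resample"):
            similarity_map(cube, three_refs[0], "pearson")


class TestClassifySimilarity:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.85, "pesticide"), (0.65, "suspected"), (0.80, "suspected"),
         (0.50, "suspected"), (0.49, "background")],
    )
    def test_published_threshold_rule(self, value, expected):
        sim = SimilarityMap(values=np.array([[value]]), metric="pearson",
                            reference_name="x")
        lab = classify_similarity(sim)
        assert lab.labels[0, 0] == expected

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(10)
        sim = SimilarityMap(values=rng.uniform(-1, 1, (20, 20)), metric="pearson",
                            reference_name="x")
        lab = classify_similarity(sim)
        counts = {c: int(np.sum(lab.labels == c)) for c in lab.categories}
        assert sum(counts.values()) == 400


class TestMixedOverlap:
    def _mixture_cube(self, three_refs, axis128):
        """Pixels: pure A, pure B, both, and background-only."""
        a = three_refs[0].spectrum.intensities
        b = three_refs[1].spectrum.intensities
        bg = 1e-3 * np.ones_like(a)
        X = np.vstack([a, b, a + b, bg])
        return _cube_of(X, axis128, 2, 2)

    def test_additive_color_codes(self, three_refs, axis128):
        # threshold low enough that a 50/50 mixture registers against both
        cube = self._mixture_cube(three_refs, axis128)
        cfg = PipelineConfig(pesticide_threshold=0.55, suspected_threshold=0.3)
        lab = mixed_overlap_map(cube, three_refs[0], three_refs[1], cfg,
                                correct_baseline=False)
        codes = lab.color_values.ravel()
        assert codes[0] == 10  # A only
        assert codes[1] == 20  # B only
        assert codes[2] == 30  # overlap: sum of codes
        assert codes[3] == 0  # nothing

    def test_code_set_is_closed(self, three_refs):
        scene = default_scene(seed=12, n_depth=10, n_lateral=10)
        from serspen import assemble_hypermap, make_reference_spectrum
        cube, _ = assemble_hypermap(scene, 24.0)
        refs = [make_reference_spectrum(c.peaks, scene.axis, name=c.name)
                for c in scene.components]
        lab = mixed_overlap_map(cube, refs[0], refs[1])
        assert set(np.unique(lab.color_values)) <= {0, 10, 20, 30}

    def test_identical_references_rejected(self, three_refs, axis128):
        cube = self._mixture_cube(three_refs, axis128)
        with pytest.raises(DomainError):
            mixed_overlap_map(cube, three_refs[0], three_refs[0])

    def test_custom_codes_respected(self, three_refs, axis128):
        cube = self._mixture_cube(three_refs, axis128)
        cfg = PipelineConfig(
            pesticide_threshold=0.55, suspected_threshold=0.3,
            color_codes={"none": 0, "pesticide_a": 3, "pesticide_b": 7},
        )
        lab = mixed_overlap_map(cube, three_refs[0], three_refs[1], cfg,
                                correct_baseline=False)
        assert set(np.unique(lab.color_values)) == {0, 3, 7, 10}
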