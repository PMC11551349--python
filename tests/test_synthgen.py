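import numpy as np
import pytest

from ramanmix import synthgen
from ramanmix.core import AbundanceMap, EndmemberSet
from ramanmix.errors import ParameterError
from ramanmix.synthgen import (
    ArtifactParams,
    EndmemberSamplerParams,
    SceneParams,
    add_artifacts,
    generate_dataset,
    make_scene,
    mix,
    sample_endmember,
)

from conftest import random_dataset


class TestEndmemberSampler:
    def test_major_peak_count_in_stated_range(self, rng):
        params = EndmemberSamplerParams(b=200, n=1)
        for _ in range(50):
            _, (major, small) = sample_endmember(params, rng, return_peaks=True)
            assert 5 <= major.heights.size <= 9
            assert small is None

    def test_noisy_small_peak_count_in_stated_range(self, rng):
        params = EndmemberSamplerParams(b=200, n=1, noisy=True)
        for _ in range(50):
            _, (_, small) = sample_endmember(params, rng, return_peaks=True)
            assert 50 <= small.heights.size <= 99
            np.testing.assert_allclose(small.h1, 1.0 / 3.0)

    def test_h1_monte_carlo_mean_matches_beta_law(self, rng):
        # h1 = 1 + 5*Beta(1,3): mean 2.25, sd 5*sqrt(3/80).
        params = EndmemberSamplerParams(b=64, n=1)
        h1 = []
        while len(h1) < 10_000:
            _, (major, _) = sample_endmember(params, rng, return_peaks=True)
            h1.extend(major.h1.tolist())
        h1 = np.array(h1[:10_000])
        se = 5.0 * np.sqrt(3.0 / 80.0) / np.sqrt(h1.size)
        assert abs(h1.mean() - 2.25) < 3.0 * se

    def test_peak_heights_widths_centers_follow_law(self, rng):
        params = EndmemberSamplerParams(b=500, n=1)
        _, (major, _) = sample_endmember(params, rng, return_peaks=True)
        np.testing.assert_allclose(major.heights, major.h1 * major.h2)
        assert np.all((major.h2 >= 0.1) & (major.h2 <= 1.0))
        assert np.all((major.widths >= 0.1) & (major.widths <= 1.0))
        assert np.all((major.centers >= 10.0) & (major.centers <= 490.0))

    def test_vector_is_nonnegative_superposition(self, rng):
        params = EndmemberSamplerParams(b=128, n=1)
        spectrum, (major, _) = sample_endmember(params, rng, return_peaks=True)
        assert spectrum.shape == (128,)
        assert np.all(spectrum >= 0)
        j = np.arange(1, 129, dtype=float)
        expected = sum(
            h * np.exp(-((j - c) ** 2) / (2 * w**2))
            for h, c, w in zip(major.heights, major.centers, major.widths)
        )
        np.testing.assert_allclose(spectrum, expected)

    def test_too_few_bands_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_endmember(EndmemberSamplerParams(b=15, n=1), rng)


class TestScenes:
    def test_chessboard_patches_are_constant_one_hot(self, rng):
        A = make_scene(SceneParams(kind="chessboard", H=100, W=100, patch=20), 5, rng)
        grid = A.values.reshape(100, 100, 5)
        for pr in range(5):
            for pc in range(5):
                block = grid[pr * 20 : (pr + 1) * 20, pc * 20 : (pc + 1) * 20]
                first = block[0, 0]
                assert np.all(block == first)
                assert first.sum() == 1.0 and set(first) <= {0.0, 1.0}

    @pytest.mark.parametrize("kind", ["chessboard", "gaussian", "dirichlet"])
    def test_every_scene_satisfies_anc_asc(self, rng, kind):
        A = make_scene(SceneParams(kind=kind, H=20, W=20, patch=5), 4, rng)
        assert np.all(A.values >= 0)
        np.testing.assert_allclose(A.values.sum(axis=1), 1.0, atol=1e-12)
        assert A.violations() == []

    def test_dirichlet_component_means_near_uniform(self, rng):
        n = 5
        A = make_scene(SceneParams(kind="dirichlet", H=100, W=100), n, rng)
        # Dirichlet(1,..,1) marginal: mean 1/n, var (n-1)/(n^2 (n+1)).
        se = np.sqrt((n - 1) / (n**2 * (n + 1))) / np.sqrt(A.n_spectra)
        assert np.all(np.abs(A.values.mean(axis=0) - 1.0 / n) < 3.0 * se)

    def test_gaussian_scene_components_dominate_at_their_diagonal_center(self, rng):
        n = 3
        A = make_scene(SceneParams(kind="gaussian", H=30, W=30), n, rng)
        grid = A.values.reshape(30, 30, n)
        for k in range(n):
            center = int((k + 0.5) * 30 / n)  # bump center on the diagonal
            assert np.argmax(grid[center, center]) == k

    def test_chessboard_patch_must_divide(self, rng):
        with pytest.raises(ParameterError):
            make_scene(SceneParams(kind="chessboard", H=10, W=10, patch=3), 2, rng)


class TestMixing:
    @pytest.fixture
    def two_endmembers(self, rng):
        return EndmemberSet(rng.random((2, 16)) + 0.1)

    def test_one_hot_kills_fan_interactions(self, two_endmembers):
        A = AbundanceMap(np.array([[1.0, 0.0]]))
        out = mix(two_endmembers, A, "fan")
        np.testing.assert_allclose(out.intensities[0], two_endmembers.signatures[0])

    def test_fan_half_half_closed_form(self, two_endmembers):
        m1, m2 = two_endmembers.signatures
        A = AbundanceMap(np.array([[0.5, 0.5]]))
        out = mix(two_endmembers, A, "fan")
        expected = 0.5 * m1 + 0.5 * m2 + 0.5 * m1 * m2
        np.testing.assert_allclose(out.intensities[0], expected, rtol=1e-12)

    def test_chessboard_linear_mix_yields_pure_endmembers(self, tiny_chessboard):
        d, record = tiny_chessboard
        labels = np.argmax(record.abundances.values, axis=1)
        np.testing.assert_array_equal(
            d.intensities, record.endmembers.signatures[labels]
        )

    def test_dimension_mismatch_rejected(self, two_endmembers):
        from ramanmix.errors import DimensionError

        with pytest.raises(DimensionError):
            mix(two_endmembers, AbundanceMap(np.ones((1, 3)) / 3))


class TestArtifacts:
    def test_baseline_closed_form_at_last_band(self, rng):
        d = random_dataset(rng, 5, 100)
        params = ArtifactParams(sigma_noise=0.0, p_baseline=1.0, p_spike=0.0)
        out, flags = add_artifacts(d, params, rng)
        added = out.intensities - d.intensities
        assert flags.baseline_added.all()
        # B_j = h_B * arctan(pi * j / b); at j = b this is 2*arctan(pi).
        np.testing.assert_allclose(added[:, -1], 2.0 * np.arctan(np.pi), rtol=1e-12)
        np.testing.assert_allclose(
            added[:, 0], 2.0 * np.arctan(np.pi / 100), rtol=1e-12
        )

    def test_all_probabilities_zero_is_identity(self, rng):
        d = random_dataset(rng, 5, 50)
        params = ArtifactParams(sigma_noise=0.0, p_baseline=0.0, p_spike=0.0)
        out, flags = add_artifacts(d, params, rng)
        np.testing.assert_array_equal(out.intensities, d.intensities)
        assert not flags.baseline_added.any() and not flags.spike_added.any()

    def test_spike_magnitude_and_band_law(self, rng):
        d = random_dataset(rng, 2000, 64)
        params = ArtifactParams(sigma_noise=0.0, p_baseline=0.0, p_spike=1.0)
        out, flags = add_artifacts(d, params, rng)
        assert flags.spike_added.all()
        rows = np.arange(d.n_spectra)
        mags = (out.intensities - d.intensities)[rows, flags.spike_band]
        assert np.all((mags >= 5.0 * 0.75) & (mags <= 5.0 * 1.25))
        # 1-based law U{2..b-2} -> 0-based indices 1..b-3.
        assert flags.spike_band.min() >= 1
        assert flags.spike_band.max() <= 64 - 3

    def test_hit_rates_within_three_binomial_se(self, rng):
        d = random_dataset(rng, 10_000, 32)
        params = ArtifactParams()
        _, flags = add_artifacts(d, params, rng)
        for frac, p in (
            (flags.baseline_added.mean(), params.p_baseline),
            (flags.spike_added.mean(), params.p_spike),
        ):
            se = np.sqrt(p * (1 - p) / d.n_spectra)
            assert abs(frac - p) < 3.0 * se


class TestGenerateDataset:
    def test_same_seed_is_bit_identical(self, small_params):
        kw = dict(
            endmember_params=small_params,
            scene_params=SceneParams(kind="gaussian", H=8, W=8),
        )
        d1, r1 = generate_dataset("realistic", "gaussian", seed=7, **kw)
        d2, r2 = generate_dataset("realistic", "gaussian", seed=7, **kw)
        np.testing.assert_array_equal(d1.intensities, d2.intensities)
        np.testing.assert_array_equal(
            r1.endmembers.signatures, r2.endmembers.signatures
        )
        np.testing.assert_array_equal(
            r1.artifact_flags.spike_band, r2.artifact_flags.spike_band
        )

    def test_ideal_dataset_reconstructs_from_record(self, tiny_chessboard):
        d, record = tiny_chessboard
        rebuilt = mix(record.endmembers, record.abundances, record.mixture_model)
        np.testing.assert_array_equal(rebuilt.intensities, d.intensities)

    def test_bilinear_chessboard_rejected(self):
        with pytest.raises(ParameterError, match="bilinear"):
            generate_dataset("bilinear", "chessboard", seed=0)

    def test_eleven_variants_enumerated(self):
        variants = synthgen.dataset_variants()
        assert len(variants) == 11
        assert ("bilinear", "chessboard") not in variants

    def test_full_coverage_redraw(self, small_params):
        # 2x2 patches with 3 endmembers frequently miss one; coverage flag
        # must still deliver all of them.
        sp = SceneParams(kind="chessboard", H=4, W=4, patch=2)
        for seed in range(10):
            _, record = generate_dataset(
                "ideal", "chessboard", seed=seed,
                endmember_params=small_params, scene_params=sp,
                require_full_coverage=True,
            )
            present = np.unique(np.argmax(record.abundances.values, axis=1))
            assert present.size == 3

    def test_scenario_stage_independence(self, small_params):
        # Same seed, different scenario: ground-truth scenes share the
        # abundance stream (artifact stream must not perturb it).
        sp = SceneParams(kind="dirichlet", H=6, W=6)
        _, r_ideal = generate_dataset(
            "ideal", "dirichlet", seed=11,
            endmember_params=small_params, scene_params=sp,
        )
        _, r_art = generate_dataset(
            "artifacts", "dirichlet", seed=11,
            endmember_params=small_params, scene_params=sp,
        )
        np.testing.assert_array_equal(
            r_ideal.abundances.values, r_art.abundances.values
        )
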