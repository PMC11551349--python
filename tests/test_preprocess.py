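import numpy as np
import pytest

from ramanmix.core import SpectralAxis, SpectralDataset
from ramanmix.errors import (
    DegenerateRangeError,
    EmptyRangeError,
    ParameterError,
)
from ramanmix.preprocess import (
    PRESETS,
    Pipeline,
    baseline_correct,
    crop,
    denoise_savgol,
    despike,
    normalize,
    preset_pipeline,
)
from ramanmix.synthgen import (
    ArtifactParams,
    EndmemberSamplerParams,
    sample_endmember,
)


def _make(intens, axis=None):
    intens = np.atleast_2d(intens)
    if axis is None:
        axis = np.arange(1, intens.shape[1] + 1, dtype=float)
    return SpectralDataset(intens, SpectralAxis(axis))


@pytest.fixture
def sugar_axis_dataset(rng):
    # mimics a raw acquisition axis spanning 142 to 3684.8 cm^-1
    axis = np.linspace(142.0, 3684.8, 500)
    return _make(rng.random((4, 500)), axis)


class TestCrop:
    def test_closed_interval_selection(self, sugar_axis_dataset):
        out = crop(sugar_axis_dataset, 400.0, 1800.0)
        assert np.all((out.axis.values >= 400.0) & (out.axis.values <= 1800.0))
        assert out.n_spectra == sugar_axis_dataset.n_spectra
        kept = (sugar_axis_dataset.axis.values >= 400.0) & (
            sugar_axis_dataset.axis.values <= 1800.0
        )
        assert out.n_bands == kept.sum()

    def test_full_range_is_identity(self, sugar_axis_dataset):
        out = crop(sugar_axis_dataset, 0.0, 5000.0)
        np.testing.assert_array_equal(out.intensities, sugar_axis_dataset.intensities)

    def test_empty_range_raises(self, sugar_axis_dataset):
        with pytest.raises(EmptyRangeError):
            crop(sugar_axis_dataset, 5000.0, 6000.0)


class TestDespike:
    def test_smooth_spectrum_unchanged(self, rng):
        x = np.linspace(-3, 3, 200)
        smooth = np.exp(-(x**2)) * 5 + 1
        out = despike(_make(smooth))
        np.testing.assert_allclose(out.intensities[0], smooth, atol=1e-12)

    def test_flat_spectrum_spike_restored(self):
        y = np.full(100, 2.0)
        y[40] += 7.0
        out = despike(_make(y))
        np.testing.assert_allclose(out.intensities[0], 2.0, atol=1e-9)

    def test_generated_spike_suppressed_below_threshold(self, rng):
        spectrum = sample_endmember(EndmemberSamplerParams(b=300, n=1), rng)
        spectrum = spectrum + 0.5  # offset so MAD is finite but small
        spiked = spectrum.copy()
        spiked[150] += 5.0  # synthetic cosmic spike, h_S scale
        out = despike(_make(spiked), kernel=3, z_threshold=8.0)
        diff = np.diff(out.intensities[0])
        mad = np.median(np.abs(diff - np.median(diff))) or np.finfo(float).tiny
        z = 0.6745 * (diff - np.median(diff)) / mad
        assert np.abs(z).max() < 8.0


class TestSavgol:
    def test_cubic_polynomial_reproduced(self):
        j = np.arange(50, dtype=float)
        cubic = 0.01 * j**3 - 0.3 * j**2 + j + 5
        out = denoise_savgol(_make(cubic), window=7, polyorder=3)
        np.testing.assert_allclose(out.intensities[0], cubic, rtol=1e-10)

    def test_noise_variance_reduced(self, rng):
        noise = rng.normal(0, 1, size=(20, 400))
        out = denoise_savgol(_make(noise))
        assert out.intensities.var() < noise.var()

    def test_constant_unchanged(self):
        out = denoise_savgol(_make(np.full(30, 4.2)))
        np.testing.assert_allclose(out.intensities[0], 4.2)

    def test_window_larger_than_bands_rejected(self, rng):
        with pytest.raises(ParameterError):
            denoise_savgol(_make(rng.random(5)), window=7)


class TestBaselineCorrection:
    @pytest.mark.parametrize("method,lam,p", [("asls", 1e6, 0.01), ("aspls", 1e5, None)])
    def test_pure_arctan_baseline_removed(self, method, lam, p):
        b = 1000  # the generator's default band count
        j = np.arange(1, b + 1, dtype=float)
        baseline = 2.0 * np.arctan(np.pi * j / b)  # the generator's shape
        out = baseline_correct(
            _make(baseline), method=method, lam=lam, p=p, max_iter=100
        )
        assert np.abs(out.intensities[0]).max() <= 0.05 * 2.0

    def test_zero_spectrum_stays_zero(self):
        out = baseline_correct(_make(np.zeros(100)), method="asls", lam=1e5, p=0.01)
        np.testing.assert_allclose(out.intensities[0], 0.0, atol=1e-10)

    def test_peak_positions_preserved(self, rng):
        b = 400
        j = np.arange(1, b + 1, dtype=float)
        clean = np.zeros(b)
        centers = [80, 200, 320]
        for c in centers:
            clean += 5.0 * np.exp(-((j - c) ** 2) / (2 * 4.0**2))
        contaminated = clean + 2.0 * np.arctan(np.pi * j / b)
        out = baseline_correct(
            _make(contaminated), method="asls", lam=1e6, p=0.01, max_iter=100
        )
        corrected = out.intensities[0]
        for c in centers:
            window = corrected[c - 30 : c + 30]
            assert abs(int(np.argmax(window)) + c - 30 - (c - 1)) <= 2


class TestNormalize:
    def test_minmax_hits_zero_and_one(self, rng):
        out = normalize(_make(rng.random((5, 40)) * 7 - 2), mode="global_minmax")
        assert out.intensities.min() == 0.0 and out.intensities.max() == 1.0

    def test_minmax_idempotent(self, rng):
        d = _make(rng.random((5, 40)))
        once = normalize(d, mode="global_minmax")
        twice = normalize(once, mode="global_minmax")
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-15)

    def test_global_vector_max_magnitude_one(self, rng):
        out = normalize(_make(rng.random((5, 40)) * 9 - 3), mode="global_vector")
        assert np.abs(out.intensities).max() == 1.0

    def test_constant_dataset_minmax_rejected(self):
        with pytest.raises(DegenerateRangeError):
            normalize(_make(np.full((3, 10), 2.0)), mode="global_minmax")


class TestPipelines:
    @pytest.fixture
    def realistic_fixture(self, rng):
        from ramanmix.synthgen import SceneParams, generate_dataset

        d, _ = generate_dataset(
            "realistic",
            "dirichlet",
            seed=0,
            endmember_params=EndmemberSamplerParams(b=300, n=3),
            scene_params=SceneParams(kind="dirichlet", H=4, W=4),
        )
        # place the synthetic axis inside both preset crop windows
        axis = np.linspace(300.0, 1900.0, 300)
        return SpectralDataset(d.intensities, SpectralAxis(axis))

    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_presets_run_end_to_end_with_log(self, realistic_fixture, preset):
        pipe = preset_pipeline(preset)
        out = pipe(realistic_fixture)
        assert out.n_spectra == realistic_fixture.n_spectra
        assert 0 < out.n_bands < realistic_fixture.n_bands  # crop applied
        assert len(pipe.log) == len(PRESETS[preset].steps)
        assert all("->" in line for line in pipe.log)

    def test_cell_preset_output_in_unit_interval(self, realistic_fixture):
        out = preset_pipeline("cell")(realistic_fixture)
        assert out.intensities.min() == 0.0 and out.intensities.max() == 1.0

    def test_unknown_step_rejected(self):
        from ramanmix.preprocess import PipelineConfig

        with pytest.raises(ParameterError):
            Pipeline(PipelineConfig(steps=[("warp", {})]))
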