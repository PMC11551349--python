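import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanmix import models
from ramanmix.core import AbundanceMap, EndmemberSet
from ramanmix.errors import (
    DimensionError,
    ModelStateError,
    UndefinedAngleError,
)
from ramanmix.models import (
    DecoderSpec,
    TrainingConfig,
    UnmixingAutoencoder,
    decode,
    extract_endmembers,
    fit,
    infer_abundances,
    sad,
    soft_rectified_tanh,
    training_loss,
)
from ramanmix.synthgen import mix


class TestSoftRectifiedTanh:
    def test_closed_form_values(self):
        assert np.isclose(soft_rectified_tanh(0.0), np.log(2.0) / 10.0)
        assert np.isclose(soft_rectified_tanh(100.0), np.log(1 + np.e**10) / 10.0)
        assert np.isclose(soft_rectified_tanh(-100.0), np.log(1 + np.e**-10) / 10.0)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(deadline=None)
    def test_positive_and_monotone(self, a, b):
        ya, yb = soft_rectified_tanh(a), soft_rectified_tanh(b)
        assert ya > 0 and yb > 0
        if a < b:
            assert ya <= yb

    def test_range_upper_bound(self):
        x = np.linspace(-20, 20, 1001)
        y = soft_rectified_tanh(x)
        assert y.max() <= np.log(1 + np.e**10) / 10.0 + 1e-12  # ~1.0000454


class TestSad:
    def test_identity_is_zero(self, rng):
        v = rng.random(50) + 0.1
        assert sad(v, v) == 0.0

    def test_orthogonal_is_half_pi(self):
        assert np.isclose(sad([1.0, 0.0], [0.0, 1.0]), np.pi / 2)

    def test_45_degrees(self):
        assert np.isclose(sad([1.0, 0.0], [1.0, 1.0]), np.pi / 4)

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None)
    def test_scale_invariance(self, c):
        a = np.array([1.0, 2.0, 0.5])
        b = np.array([0.3, 1.0, 2.0])
        assert np.isclose(sad(a, c * b), sad(a, b), atol=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.random(20), rng.random(20)
        assert sad(a, b) == sad(b, a)

    def test_zero_norm_raises(self):
        with pytest.raises(UndefinedAngleError):
            sad(np.zeros(4), np.ones(4))


class TestTrainingLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.random((4, 8)) + 0.1
        assert training_loss(x, x, TrainingConfig()) == 0.0
        assert training_loss(x, x, TrainingConfig(loss="sad_plus_mse")) == 0.0

    def test_sad_mode_scale_invariant(self, rng):
        x = rng.random((4, 8)) + 0.1
        assert np.isclose(training_loss(x, 2 * x, TrainingConfig()), 0.0, atol=1e-7)

    def test_sad_plus_mse_hand_computed(self):
        x = np.array([[1.0, 0.0]])
        x_hat = np.array([[1.0, 1.0]])
        cfg = TrainingConfig(loss="sad_plus_mse", lambda_mse=1000.0)
        # SAD = pi/4; MSE over bands = (0 + 1)/2; total = pi/4 + 500.
        assert np.isclose(training_loss(x, x_hat, cfg), np.pi / 4 + 500.0)


class TestDecode:
    def test_one_hot_returns_column(self, rng):
        W = rng.random((16, 3))
        for kind in ("linear", "fan_bilinear"):
            z = np.eye(3)[1]
            np.testing.assert_allclose(
                decode(z, DecoderSpec(kind, W)), W[:, 1], rtol=1e-14
            )

    def test_zero_latent_gives_zero(self, rng):
        W = rng.random((16, 3))
        for kind in ("linear", "fan_bilinear"):
            np.testing.assert_array_equal(decode(np.zeros(3), DecoderSpec(kind, W)), 0.0)

    def test_fan_decoder_mirrors_fan_mixer(self, rng):
        # Cross-module oracle: decoder with W = M^T must equal the mixer.
        M = EndmemberSet(rng.random((4, 32)))
        z = rng.dirichlet(np.ones(4))
        via_decoder = decode(z, DecoderSpec("fan_bilinear", M.signatures.T))
        via_mixer = mix(M, AbundanceMap(z[None]), "fan").intensities[0]
        np.testing.assert_array_equal(via_decoder, via_mixer)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(DimensionError):
            decode(np.ones(2), DecoderSpec("linear", rng.random((8, 3))))


class TestTraining:
    def test_loss_decreases_on_pure_pixel_data(self, tiny_chessboard):
        d, _ = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, seed=0)
        trace = fit(model, d, TrainingConfig(epochs=10, seed=0))
        assert trace[-1] < trace[0]

    def test_decoder_nonnegative_at_every_checkpoint(self, tiny_chessboard):
        d, _ = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, seed=1)
        mins = []
        fit(
            model,
            d,
            TrainingConfig(epochs=4, seed=1),
            epoch_callback=lambda e, m: mins.append(m.W.data.min()),
        )
        assert len(mins) == 4
        assert all(m >= 0.0 for m in mins)

    def test_same_seed_gives_identical_traces(self, tiny_chessboard):
        d, _ = tiny_chessboard
        traces = []
        for _ in range(2):
            model = UnmixingAutoencoder(d.n_bands, 3, seed=5)
            traces.append(fit(model, d, TrainingConfig(epochs=3, seed=5)))
        assert traces[0] == traces[1]

    def test_different_seeds_differ(self, tiny_chessboard):
        d, _ = tiny_chessboard
        t1 = fit(
            UnmixingAutoencoder(d.n_bands, 3, seed=0), d, TrainingConfig(epochs=2, seed=0)
        )
        t2 = fit(
            UnmixingAutoencoder(d.n_bands, 3, seed=9), d, TrainingConfig(epochs=2, seed=9)
        )
        assert t1 != t2

    def test_zero_spectrum_rejected(self, tiny_chessboard):
        d, _ = tiny_chessboard
        bad = d.intensities.copy()
        bad[3] = 0.0
        from ramanmix.core import SpectralDataset

        with pytest.raises(UndefinedAngleError):
            fit(
                UnmixingAutoencoder(d.n_bands, 3, seed=0),
                SpectralDataset(bad, d.axis),
                TrainingConfig(epochs=1),
            )

    def test_band_mismatch_rejected(self, tiny_chessboard):
        d, _ = tiny_chessboard
        with pytest.raises(DimensionError):
            fit(UnmixingAutoencoder(d.n_bands + 1, 3, seed=0), d)

    @pytest.mark.parametrize("loss", ["sad", "sad_plus_mse"])
    def test_both_loss_modes_train(self, tiny_chessboard, loss):
        d, _ = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, seed=0)
        trace = fit(model, d, TrainingConfig(epochs=2, seed=0, loss=loss))
        assert np.isfinite(trace).all()


class TestExtraction:
    @pytest.fixture
    def fitted(self, tiny_chessboard):
        d, record = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, seed=0)
        fit(model, d, TrainingConfig(epochs=5, seed=0))
        return model, d, record

    def test_asc_rows_sum_to_one(self, fitted):
        model, d, _ = fitted
        A = infer_abundances(model, d)
        np.testing.assert_allclose(A.values.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(A.values >= 0)

    def test_anc_only_range(self, tiny_chessboard):
        d, _ = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, asc=False, seed=0)
        fit(model, d, TrainingConfig(epochs=2, seed=0))
        A = infer_abundances(model, d)
        upper = np.log(1 + np.e**10) / 10.0  # soft-rectified tanh ceiling
        assert np.all(A.values > 0) and np.all(A.values <= upper)
        assert not A.asc

    def test_extracted_endmembers_nonnegative(self, fitted):
        model, _, _ = fitted
        M = extract_endmembers(model)
        assert np.all(M.signatures >= 0)
        assert M.signatures.shape == (3, 64)

    def test_unfitted_model_raises_state_error(self, tiny_chessboard):
        d, _ = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, seed=0)
        with pytest.raises(ModelStateError):
            extract_endmembers(model)
        with pytest.raises(ModelStateError):
            infer_abundances(model, d)

    def test_frozen_decoder_performs_nonblind_unmixing(self, tiny_chessboard):
        d, record = tiny_chessboard
        model = UnmixingAutoencoder(
            d.n_bands,
            3,
            seed=0,
            init_endmembers=record.endmembers,
            freeze_decoder=True,
        )
        fit(model, d, TrainingConfig(epochs=3, seed=0))
        np.testing.assert_array_equal(
            extract_endmembers(model).signatures, record.endmembers.signatures
        )


class TestArchitectures:
    @pytest.mark.parametrize(
        "kind", ["dense", "deep_dense", "conv", "transformer", "conv_transformer"]
    )
    def test_every_encoder_trains_and_respects_constraints(
        self, tiny_chessboard, kind
    ):
        d, _ = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, encoder=kind, seed=0)
        trace = fit(model, d, TrainingConfig(epochs=1, seed=0))
        assert np.isfinite(trace).all()
        A = infer_abundances(model, d)
        np.testing.assert_allclose(A.values.sum(axis=1), 1.0, atol=1e-6)
        assert model.W.data.min() >= 0.0

    def test_fan_decoder_trains(self, tiny_chessboard):
        d, _ = tiny_chessboard
        model = UnmixingAutoencoder(d.n_bands, 3, decoder="fan_bilinear", seed=0)
        trace = fit(model, d, TrainingConfig(epochs=2, seed=0))
        assert trace[-1] < trace[0]
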