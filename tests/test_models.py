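import numpy as np
import pytest

from periseg.network import (
    DilatedFCN,
    PatchCNN,
    TrainingConfig,
    build_baseline_cnn,
    build_dlfcnn,
    load_weights,
    output_size,
    predict_mask,
    save_weights,
    train,
)
from periseg.network.models import normalize_hu
from periseg.phantom import PhantomConfig, generate_cohort
from periseg.types import CTSlice


class TestBuildDlfcnn:
    def test_feature_map_counts_match_table(self):
        spec = build_dlfcnn()
        assert spec.feature_map_counts() == (14, 14, 14, 14, 28, 28, 28, 28, 52)

    def test_layer_names(self):
        names = [l.name for l in build_dlfcnn().layers]
        assert names == ["C1", "S2", "C3", "S4", "C5", "S6", "C7", "S8", "F9", "OUT"]

    def test_dilations_on_feature_layers(self):
        by_name = {l.name: l for l in build_dlfcnn().layers}
        assert (by_name["C3"].dilation, by_name["C5"].dilation,
                by_name["C7"].dilation) == (2, 4, 5)

    def test_forward_shape_and_range(self, rng):
        model = DilatedFCN(build_dlfcnn())
        model.init_weights(rng)
        out = model.forward(rng.random((1, 1, 64, 64)))
        assert out.shape == (1, 1, 64, 64)
        assert np.all((out > 0) & (out < 1))

    @pytest.mark.parametrize("size", [32, 64, 128])
    def test_any_input_size_accepted(self, rng, size):
        model = DilatedFCN(build_dlfcnn())
        model.init_weights(rng)
        out = model.forward(rng.random((1, 1, size, size)))
        assert out.shape == (1, 1, size, size)

    @pytest.mark.parametrize("size", [32, 64, 128])
    def test_realized_sizes_obey_output_size_formula(self, rng, size):
        model = DilatedFCN(build_dlfcnn())
        model.init_weights(rng)
        model.forward(rng.random((1, 1, size, size)))
        expected = size
        for (name, h, w), ls in zip(model.layer_output_sizes(), model.spec.layers):
            if ls.kind == "downsample":
                expected = expected // 2  # 2x2 window, stride 2
            else:
                expected = output_size(
                    expected, ls.kernel_size, ls.padding, ls.stride, ls.dilation
                )
            assert (h, w) == (expected, expected), name

    def test_too_small_input_rejected(self, rng):
        model = DilatedFCN(build_dlfcnn())
        model.init_weights(rng)
        with pytest.raises(ValueError, match="at least"):
            model.forward(rng.random((1, 1, 16, 16)))

    @pytest.mark.parametrize("mode", ["bilinear", "bilinear_skip", "transposed_conv"])
    def test_all_decode_modes_run(self, rng, mode):
        model = DilatedFCN(build_dlfcnn(upsample=mode))
        model.init_weights(rng)
        out = model.forward(rng.random((1, 1, 32, 32)))
        assert out.shape == (1, 1, 32, 32)
        model.backward(np.ones_like(out) / out.size)  # smoke the backward

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            DilatedFCN(build_dlfcnn(upsample="nearest"))


class TestBaselineCnn:
    def test_trunk_counts_match_table(self):
        spec = build_baseline_cnn(32)
        assert spec.feature_map_counts() == (14, 14, 14, 14, 28, 28, 28, 28, 52)

    def test_single_probability_per_patch(self, rng):
        model = PatchCNN(build_baseline_cnn(32))
        model.init_weights(rng)
        out = model.forward(rng.random((5, 1, 32, 32)))
        assert out.shape == (5, 1)
        assert np.all((out > 0) & (out < 1))

    def test_dense_map_shape_equals_input(self, rng):
        model = PatchCNN(build_baseline_cnn(32))
        model.init_weights(rng)
        ct = CTSlice(rng.normal(-100, 50, (40, 40)), (1, 1))
        proba = model.predict_proba(ct, stride=4)
        assert proba.shape == (40, 40)

    def test_patch_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_baseline_cnn(16)


class TestNormalization:
    def test_window_limits(self):
        assert normalize_hu(np.array([-1000.0]))[0] == 0.0
        assert normalize_hu(np.array([240.0]))[0] == 1.0
        assert normalize_hu(np.array([40.0]))[0] == pytest.approx(0.5)


class TestPredictMask:
    def test_threshold_semantics(self, rng):
        class Stub:
            def predict_proba(self, ct):
                return self._p

        stub = Stub()
        stub._p = np.full((4, 4), 0.9)
        ct = CTSlice(np.zeros((4, 4)), (1, 1))
        assert predict_mask(stub, ct, 0.5).all()
        stub._p = np.full((4, 4), 0.1)
        assert not predict_mask(stub, ct, 0.5).any()

    def test_elementwise_oracle(self, rng):
        class Stub:
            def predict_proba(self, ct):
                return self._p

        stub = Stub()
        stub._p = rng.random((6, 6))
        ct = CTSlice(np.zeros((6, 6)), (1, 1))
        mask = predict_mask(stub, ct, 0.37)
        for i in range(6):
            for j in range(6):
                assert mask[i, j] == (stub._p[i, j] > 0.37)

    def test_untrained_model_rejected(self):
        model = DilatedFCN(build_dlfcnn())
        ct = CTSlice(np.zeros((32, 32)), (1, 1))
        with pytest.raises(RuntimeError, match="no weights"):
            predict_mask(model, ct)

    def test_bad_threshold(self, rng):
        model = DilatedFCN(build_dlfcnn())
        model.init_weights(rng)
        ct = CTSlice(np.zeros((32, 32)), (1, 1))
        with pytest.raises(ValueError):
            predict_mask(model, ct, 1.5)


@pytest.fixture(scope="module")
def tiny_data():
    base = PhantomConfig(image_size=32, pixel_spacing_mm=2.0)
    samples = generate_cohort(8, 0, base, seed=77)
    return [(ct, gt.lesion_mask) for ct, gt in samples]


class TestTraining:
    def test_loss_decreases(self, tiny_data):
        model = DilatedFCN(build_dlfcnn())
        _, records = train(model, tiny_data, TrainingConfig(epochs=10, seed=1))
        assert records[-1].R < records[0].R
        assert all(np.isfinite(r.R) and r.R >= 0 for r in records)

    def test_bit_reproducible(self, tiny_data):
        runs = []
        for _ in range(2):
            model = DilatedFCN(build_dlfcnn())
            train(model, tiny_data, TrainingConfig(epochs=2, seed=3))
            runs.append([p.copy() for p in model.parameters()])
        for a, b in zip(*runs):
            assert np.array_equal(a, b)

    def test_patch_model_trains(self, tiny_data):
        model = PatchCNN(build_baseline_cnn(32))
        _, records = train(
            model,
            tiny_data,
            TrainingConfig(epochs=3, seed=1, learning_rate=0.5,
                           patches_per_image=8),
        )
        assert all(np.isfinite(r.R) for r in records)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train(DilatedFCN(build_dlfcnn()), [], TrainingConfig(epochs=1))

    def test_divergence_aborts(self):
        from periseg.network.train import _check_finite

        with pytest.raises(RuntimeError, match="diverged"):
            _check_finite(float("nan"), epoch=3)
        with pytest.raises(RuntimeError, match="diverged"):
            _check_finite(float("inf"), epoch=3)
        _check_finite(0.1, epoch=3)  # no raise


class TestWeightsRoundTrip:
    def test_fcn_round_trip(self, rng, tmp_path):
        model = DilatedFCN(build_dlfcnn())
        model.init_weights(rng)
        path = tmp_path / "w.npz"
        save_weights(model, path)
        loaded = load_weights(path)
        assert isinstance(loaded, DilatedFCN)
        x = rng.random((1, 1, 32, 32))
        assert np.array_equal(model.forward(x), loaded.forward(x))

    def test_patch_round_trip(self, rng, tmp_path):
        model = PatchCNN(build_baseline_cnn(32))
        model.init_weights(rng)
        path = tmp_path / "w.npz"
        save_weights(model, path)
        loaded = load_weights(path)
        assert isinstance(loaded, PatchCNN)
        assert loaded.patch_size == 32
        x = rng.random((2, 1, 32, 32))
        assert np.array_equal(model.forward(x), loaded.forward(x))
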