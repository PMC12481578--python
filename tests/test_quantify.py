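"""Quantification models: custom layers, architectures, ensemble protocol,
and metrics."""

import numpy as np
import pytest

from sersquant.nn import Tensor
from sersquant.quantify import (
    EvalReport,
    MultiscaleLayer,
    RegionScalingLayer,
    RegionScalingSpec,
    ThreePLHead,
    ThreePLSpec,
    TrainProtocol,
    build_model,
    evaluate,
    propose_irrelevant_regions,
    three_pl,
    train_ensemble,
)
from sersquant.spectra import LabelledDataset, Spectrum, SpectrumState

from conftest import make_uniform_spectrum


class TestThreePL:
    def test_midpoint_maps_to_half_upper(self):
        spec = ThreePLSpec(upper=10.0, midpoint=1.3, steepness=2.0)
        assert three_pl(1.3, spec) == pytest.approx(5.0)

    def test_asymptotes(self):
        spec = ThreePLSpec(upper=8.0)
        assert three_pl(-50.0, spec) == pytest.approx(0.0, abs=1e-12)
        assert three_pl(50.0, spec) == pytest.approx(8.0, abs=1e-12)

    def test_strictly_increasing(self):
        z = np.linspace(-6, 6, 200)
        out = three_pl(z, ThreePLSpec(upper=10, midpoint=0.5, steepness=1.5))
        assert np.all(np.diff(out) > 0)

    def test_invalid_steepness_rejected(self):
        with pytest.raises(ValueError):
            ThreePLSpec(steepness=0.0)

    def test_learnable_head_bounded_by_upper(self, rng):
        head = ThreePLHead(ThreePLSpec(upper=10.0))
        z = Tensor(rng.normal(scale=5.0, size=100))
        out = head(z).data
        assert np.all(out > 0)
        assert np.all(out < 10.0)


class TestMultiscaleLayer:
    def test_output_shape_24_channels(self, rng):
        layer = MultiscaleLayer(1, rng)
        out = layer(Tensor(rng.normal(size=(2, 937, 1))))
        assert out.shape == (2, 937, 24)

    def test_zero_input_zero_bias_gives_zero(self, rng):
        layer = MultiscaleLayer(1, rng)
        for c in layer.convs:
            c.b.data[:] = 0.0
        out = layer(Tensor(np.zeros((1, 100, 1))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_impulse_response_matches_direct_correlation(self, rng):
        layer = MultiscaleLayer(1, rng)
        L = 120
        pos = 60
        x = np.zeros((1, L, 1))
        x[0, pos, 0] = 1.0
        out = layer(Tensor(x)).data[0]
        # cross-correlation oracle: y[l] = sum_k x[l + k - pl] w[k]
        col = 0
        for conv in layer.convs:
            K = conv.kernel
            pl = (K - 1) // 2
            for f in range(conv.w.data.shape[2]):
                expected = np.zeros(L)
                for l in range(L):
                    k = pos - l + pl
                    if 0 <= k < K:
                        expected[l] = conv.w.data[k, 0, f]
                np.testing.assert_allclose(
                    out[:, col] - conv.b.data[f], expected, atol=1e-12
                )
                col += 1

    def test_input_shorter_than_kernel_rejected(self, rng):
        layer = MultiscaleLayer(1, rng)
        with pytest.raises(ValueError, match="kernel"):
            layer(Tensor(np.zeros((1, 30, 1))))

    def test_linearity_superposition(self, rng):
        layer = MultiscaleLayer(1, rng)
        for c in layer.convs:
            c.b.data[:] = 0.0
        a = rng.normal(size=(1, 80, 1))
        b = rng.normal(size=(1, 80, 1))
        out_sum = layer(Tensor(a + b)).data
        np.testing.assert_allclose(
            out_sum, layer(Tensor(a)).data + layer(Tensor(b)).data, atol=1e-10
        )


class TestRegionScaling:
    def test_unit_scales_are_identity(self, rng):
        spec = RegionScalingSpec(regions=((5, 15), (30, 40)), scale_init=1.0)
        layer = RegionScalingLayer(spec, 50)
        x = rng.normal(size=(2, 50, 3))
        np.testing.assert_allclose(layer(Tensor(x)).data, x)

    def test_full_region_zero_scale_zeroes(self, rng):
        spec = RegionScalingSpec(regions=((0, 20),), scale_init=0.0)
        layer = RegionScalingLayer(spec, 20)
        out = layer(Tensor(rng.normal(size=(1, 20, 2))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_piecewise_pattern(self):
        spec = RegionScalingSpec(regions=((0, 3), (5, 8)), scale_init=(2.0, 3.0))
        layer = RegionScalingLayer(spec, 10)
        out = layer(Tensor(np.ones((1, 10, 1)))).data[0, :, 0]
        np.testing.assert_allclose(out, [2, 2, 2, 1, 1, 3, 3, 3, 1, 1])

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionScalingSpec(regions=((0, 10), (5, 15)))

    def test_region_outside_length_rejected(self):
        spec = RegionScalingSpec(regions=((0, 30),))
        with pytest.raises(ValueError, match="outside"):
            RegionScalingLayer(spec, 20)


class TestBuildModel:
    def test_cnn_3pl_untrained_predictions_bounded(self, rng):
        m = build_model("cnn_3pl", 128, seed=0)
        pred = m.predict(rng.uniform(0, 1, size=(6, 128)))
        assert np.all(pred > 0)
        assert np.all(pred < float(m.head.upper.data))

    def test_scnn_identity_scaling_matches_unscaled_path(self, rng):
        m = build_model("scnn", 128, seed=4)
        x = rng.uniform(0, 1, size=(3, 128))
        base = m.predict(x)
        m.region_scaling.scales.data[:] = 1.0
        np.testing.assert_allclose(m.predict(x), base)

    @pytest.mark.parametrize(
        "dim,expected", [(925, 37), (937, 38), (842, 34)]
    )
    def test_vit_patch_count(self, dim, expected):
        m = build_model("vit", dim, seed=0)
        assert m.n_patches == expected

    def test_vit_forward_shape(self, rng):
        m = build_model("vit", 130, seed=0)
        assert m.predict(rng.uniform(size=(4, 130))).shape == (4,)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("mlp", 100)

    def test_wrong_input_dim_rejected(self, rng):
        m = build_model("cnn_linear", 128, seed=0)
        with pytest.raises(ValueError, match="input dim"):
            m.predict(rng.uniform(size=(2, 100)))


def _easy_dataset(n=40, dim=96, seed=0):
    """Targets are a fixed linear readout of the spectrum: learnable fast."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, dim))
    y = 4.0 * X[:, 10] + 2.0
    spectra = [make_uniform_spectrum(x, SpectrumState.NORMALIZED) for x in X]
    ids = np.array([f"S{i}" for i in range(n)], object)
    return LabelledDataset(spectra, y, ids)


class TestTrainEnsemble:
    def test_selection_is_argmin_validation_mae(self):
        tr = _easy_dataset(40, seed=0)
        va = _easy_dataset(16, seed=1)
        proto = TrainProtocol(ensemble_size=3, epochs=30, drop_threshold=np.inf)
        result = train_ensemble("cnn_linear", tr, va, proto, seed=2)
        assert result.converged
        vals = [result.histories[j]["best_val_mae"] for j in result.survivor_indices]
        assert result.histories[result.selected_index]["best_val_mae"] == min(vals)

    def test_zero_drop_threshold_forces_no_convergence(self):
        tr = _easy_dataset(30, seed=0)
        va = _easy_dataset(10, seed=1)
        proto = TrainProtocol(ensemble_size=2, epochs=2, drop_threshold=0.0)
        result = train_ensemble("cnn_linear", tr, va, proto, seed=2)
        assert not result.converged
        assert result.selected is None
        with pytest.raises(RuntimeError, match="did not converge"):
            result.predict_selected(tr.intensity_matrix())

    def test_deterministic_under_master_seed(self):
        tr = _easy_dataset(30, seed=0)
        va = _easy_dataset(10, seed=1)
        proto = TrainProtocol(ensemble_size=2, epochs=3, drop_threshold=np.inf)
        a = train_ensemble("cnn_linear", tr, va, proto, seed=11)
        b = train_ensemble("cnn_linear", tr, va, proto, seed=11)
        np.testing.assert_array_equal(
            a.predict_selected(va.intensity_matrix()),
            b.predict_selected(va.intensity_matrix()),
        )

    def test_empty_dataset_rejected(self):
        tr = _easy_dataset(10, seed=0)
        empty = tr.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="nonempty"):
            train_ensemble("cnn_linear", empty, tr, TrainProtocol(), seed=0)


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = evaluate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert (rep.mae, rep.mse, rep.mpe) == (0.0, 0.0, 0.0)

    def test_known_values(self):
        rep = evaluate(np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        assert rep.mae == pytest.approx(1.0)
        assert rep.mse == pytest.approx(1.0)

    def test_mpe_floor_excludes_zero_truth(self):
        pred = np.array([0.5, 2.0, 4.0])
        truth = np.array([0.0, 2.0, 5.0])
        rep = evaluate(pred, truth, mpe_floor=0.5)
        expected = np.mean([0.0 / 2.0, 1.0 / 5.0]) * 100
        assert rep.mpe == pytest.approx(expected)

    def test_mpe_undefined_when_all_below_floor(self):
        rep = evaluate(np.array([0.1]), np.array([0.0]))
        assert rep.mpe is None
        assert rep.mae >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros(3), np.zeros(2))


class TestProposeRegions:
    def test_regions_cover_weak_reference_stretches(self):
        x = np.arange(300.0)
        ref1 = np.exp(-0.5 * ((x - 50) / 5) ** 2)
        ref2 = np.exp(-0.5 * ((x - 250) / 5) ** 2)
        spec = propose_irrelevant_regions([ref1, ref2], fraction=0.3, min_width=20)
        assert len(spec.regions) >= 1
        for a, b in spec.regions:
            assert ref1[a:b].max() < ref1.max() / 2
            assert ref2[a:b].max() < ref2.max() / 2
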