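"""Tests of the channel-combination layer, CNN variants, and RoR baseline."""

import numpy as np
import pytest

from oxicam import nn
from oxicam.models import (
    ModelConfig,
    RatioOfRatiosCalibration,
    build_model,
    channel_combination_forward,
    compute_ac_dc,
    fit_ror_calibration,
    ratio_of_ratios,
)
from oxicam.preprocessing import SegmentSet


def scalar_channel_combination(U, W, b, relu=True):
    """Element-by-element evaluation of V = act(W U + b 1^T) (oracle)."""
    c_out, c_in = W.shape
    L = U.shape[1]
    V = np.empty((c_out, L))
    for o in range(c_out):
        for t in range(L):
            acc = b[o]
            for c in range(c_in):
                acc += W[o, c] * U[c, t]
            V[o, t] = max(acc, 0.0) if relu else acc
    return V


class TestChannelCombination:
    def test_identity_under_relu_on_nonnegative_input(self):
        U = np.abs(np.random.default_rng(0).normal(size=(3, 20)))
        V = channel_combination_forward(U, np.eye(3), np.zeros(3))
        assert np.array_equal(V, U)

    def test_difference_row_cancels_equal_channels(self):
        U = np.ones((3, 10))
        U[0] = U[1] = 5.0
        V = channel_combination_forward(U, np.array([[1.0, -1.0, 0.0]]), np.zeros(1))
        assert np.allclose(V, 0.0)

    def test_matches_scalar_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            c_in = int(rng.integers(1, 5))
            c_out = int(rng.integers(1, 5))
            L = int(rng.integers(1, 30))
            U = rng.normal(size=(c_in, L))
            W = rng.normal(size=(c_out, c_in))
            b = rng.normal(size=c_out)
            fast = channel_combination_forward(U, W, b)
            slow = scalar_channel_combination(U, W, b)
            denom = np.maximum(np.abs(slow), 1.0)
            assert np.max(np.abs(fast - slow) / denom) <= 1e-6

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            channel_combination_forward(np.zeros((3, 10)), np.zeros((2, 4)), np.zeros(2))


class TestArchitectures:
    @pytest.mark.parametrize("variant", ["model1", "model2", "model3"])
    def test_accepts_standard_input_and_outputs_scalar(self, variant):
        model = build_model(ModelConfig(variant=variant), seed=0)
        out = model.forward(np.random.default_rng(0).normal(size=(4, 3, 300)))
        assert out.shape == (4,)

    def test_parameter_count_magnitudes(self):
        # channel-mix-first ~3e4, per-channel-features ~1e4, interleaved ~3e5
        p1 = build_model(ModelConfig(variant="model1"), seed=0).n_params
        p2 = build_model(ModelConfig(variant="model2"), seed=0).n_params
        p3 = build_model(ModelConfig(variant="model3"), seed=0).n_params
        assert 1e4 < p1 < 1e5
        assert 3e3 < p2 < 3e4
        assert 1e5 < p3 < 1e6

    @pytest.mark.parametrize("variant", ["model1", "model2", "model3"])
    def test_gradients_flow_to_every_parameter(self, variant):
        rng = np.random.default_rng(3)
        model = build_model(ModelConfig(variant=variant), seed=3)
        x = rng.normal(size=(16, 3, 300))
        y = rng.normal(size=16)
        pred = model.forward(x, train=True)
        _, grad = nn.rmse_loss(pred, y)
        model.backward(grad)
        for value, g in model.parameters():
            assert np.any(g != 0), f"dead parameter of shape {value.shape}"

    def test_model2_channel_stacks_share_no_parameters(self):
        model = build_model(ModelConfig(variant="model2"), seed=0)
        stack_layer = model.layers[0]
        assert isinstance(stack_layer, nn.PerChannelStack)
        ids = []
        for sub in stack_layer.stacks:
            for layer in sub:
                ids.extend(id(v) for v, _ in layer.parameters())
        assert len(ids) == len(set(ids))

    def test_zeroed_model_outputs_head_bias(self):
        model = build_model(ModelConfig(variant="model1"), seed=0)
        for value, _ in model.parameters():
            value[...] = 0.0
        model.layers[-1].b[0] = 96.5
        out = model.forward(np.random.default_rng(1).normal(size=(5, 3, 300)))
        assert np.allclose(out, 96.5)

    def test_linear_mix_ablation_is_single_linear_layer(self):
        model = build_model(ModelConfig(variant="model1", ablation="linear_mix"), seed=0)
        first = model.layers[0]
        assert isinstance(first, nn.ChannelMix)
        assert first.activation == "identity"
        assert first.W.shape == (1, 3)
        assert not any(isinstance(l, nn.ChannelMix) for l in model.layers[1:])

    def test_dense_features_ablation_has_no_conv(self):
        model = build_model(
            ModelConfig(variant="model1", ablation="dense_features"), seed=0
        )
        assert not any(isinstance(l, nn.Conv1d) for l in model.layers)

    def test_numerical_gradients_match_backprop(self):
        rng = np.random.default_rng(7)
        cfg = ModelConfig(
            variant="model1",
            channel_layer_widths=(4, 4, 7),
            conv_filter_counts=(3, 2, 2),
            dense_widths=(5,),
            input_len=40,
        )
        model = build_model(cfg, seed=7)
        # move off exact-zero biases so no unit sits on the ReLU kink
        for value, _ in model.parameters():
            value += rng.normal(0, 0.05, size=value.shape)
        x = rng.normal(size=(3, 3, 40))
        y = rng.normal(size=3)
        pred = model.forward(x, train=True)
        _, grad = nn.rmse_loss(pred, y)
        model.backward(grad)
        for value, g in model.parameters():
            flat = value.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, orig = 1e-5, flat[idx]
                flat[idx] = orig + eps
                lp, _ = nn.rmse_loss(model.forward(x), y)
                flat[idx] = orig - eps
                lm, _ = nn.rmse_loss(model.forward(x), y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[idx]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num) + abs(ana))


class TestAcDc:
    def test_pure_sine_closed_form(self):
        t = np.arange(0, 10, 1 / 30)
        x = 100 + 2 * np.sin(2 * np.pi * 1.2 * t)
        ac, dc = compute_ac_dc(x, 30.0)
        assert dc[0] == pytest.approx(100.0, abs=1e-6)
        assert ac[0] == pytest.approx(2.0, rel=0.01)

    def test_ratio_arithmetic(self):
        # AC/DC 0.02 vs 0.01 -> RR = 2
        t = np.arange(0, 10, 1 / 30)
        wave = np.sin(2 * np.pi * 1.2 * t)
        window = np.vstack([100 * (1 + 0.02 * wave), 100 * (1 + 0.05 * wave),
                            100 * (1 + 0.01 * wave)])
        assert ratio_of_ratios(window, 30.0) == pytest.approx(2.0, rel=0.01)

    def test_generator_window_matches_perfusion_model(
        self, noiseless_sine_signal, noiseless_sine_opto
    ):
        window = noiseless_sine_signal.values[:, 300:600]
        ac, dc = compute_ac_dc(window, 30.0)
        m = noiseless_sine_opto.modulation(np.array([95.0]))[:, 0]
        expected = noiseless_sine_opto.perfusion_index * m
        assert np.allclose(ac / dc, expected, rtol=0.02)

    def test_scale_invariance_of_rr(self):
        t = np.arange(0, 10, 1 / 30)
        wave = np.sin(2 * np.pi * 1.5 * t)
        window = np.vstack([100 * (1 + 0.02 * wave), 100 * (1 + 0.05 * wave),
                            100 * (1 + 0.01 * wave)])
        scaled = window.copy()
        scaled[0] *= 3.7
        assert ratio_of_ratios(scaled, 30.0) == pytest.approx(
            ratio_of_ratios(window, 30.0), rel=1e-6
        )

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            compute_ac_dc(np.ones(60), 30.0)


def _window_set(rrs, labels, fps=30.0):
    """Synthesize raw windows with prescribed (AC/DC ratios, labels)."""
    t = np.arange(0, 10, 1 / fps)
    wave = np.sin(2 * np.pi * 1.3 * t)
    X = []
    for rr in rrs:
        X.append(
            np.vstack(
                [100 * (1 + 0.01 * rr * wave), 100 * (1 + 0.05 * wave),
                 100 * (1 + 0.01 * wave)]
            )
        )
    n = len(rrs)
    return SegmentSet(
        X=np.array(X),
        anchors=np.arange(n, dtype=float),
        labels=np.asarray(labels, dtype=float),
        recording_ids=np.full(n, "w", dtype=object),
        fps=fps,
    )


class TestRorCalibration:
    def test_two_points_interpolated_exactly(self):
        segs = _window_set([0.4, 0.8], [100.0, 90.0])
        cal = fit_ror_calibration(segs)
        assert cal.predict_rr(0.4) == pytest.approx(100.0, abs=0.05)
        assert cal.predict_rr(0.8) == pytest.approx(90.0, abs=0.05)

    def test_constant_labels_give_zero_slope(self):
        segs = _window_set([0.4, 0.6, 0.8], [95.0, 95.0, 95.0])
        cal = fit_ror_calibration(segs)
        assert cal.b == pytest.approx(0.0, abs=1e-6)
        assert cal.a == pytest.approx(95.0, abs=1e-6)

    def test_prediction_clipping(self):
        cal = RatioOfRatiosCalibration(a=110.0, b=25.0)
        assert cal.predict_rr(0.4) == 100.0  # 110 - 10 clipped
        assert cal.predict_rr(0.6) == pytest.approx(95.0)

    def test_single_window_rejected(self):
        segs = _window_set([0.4], [95.0])
        with pytest.raises(ValueError):
            fit_ror_calibration(segs)


class TestChannelLayerExport:
    def test_json_round_trip(self):
        import json

        from oxicam.models import export_channel_layer

        model = build_model(ModelConfig(variant="model1"), seed=4)
        exported = json.loads(json.dumps(export_channel_layer(model)))
        assert np.allclose(np.array(exported["W"]), model.layers[0].W)
        assert exported["activation"] == "relu"

    def test_model_without_mix_layer_rejected(self):
        from oxicam.models import export_channel_layer

        model = build_model(ModelConfig(variant="model3"), seed=0)
        with pytest.raises(ValueError):
            export_channel_layer(model)
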