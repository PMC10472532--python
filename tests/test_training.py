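"""Tests of the training loop, tuning, postprocessing, and metrics."""

import numpy as np
import pandas as pd
import pytest

from oxicam.models import ModelConfig, build_model
from oxicam.preprocessing import SegmentSet
from oxicam.signals import SpO2Trace
from oxicam.training import (
    OptimizerParams,
    compute_metrics,
    extract_channel_weights,
    moving_average,
    postprocess,
    random_guess_baseline,
    summarize_group,
    train_model,
    tune_hyperparameters,
)

TINY_CFG = ModelConfig(
    variant="model1",
    channel_layer_widths=(4, 4, 7),
    conv_filter_counts=(4, 2),
    dense_widths=(8,),
    input_len=60,
)


def tiny_dataset(n, seed=0, constant_label=None):
    """Segments whose red-channel amplitude encodes the label."""
    rng = np.random.default_rng(seed)
    t = np.arange(60) / 30.0
    X = np.empty((n, 3, 60))
    labels = np.empty(n)
    for i in range(n):
        s = rng.uniform(90, 99) if constant_label is None else constant_label
        amp = 0.5 + (99 - s) * 0.3
        X[i, 0] = amp * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi))
        X[i, 1] = 0.5 * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi))
        X[i, 2] = 0.7 * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi))
        X[i] += rng.normal(0, 0.01, (3, 60))
        labels[i] = s
    return SegmentSet(
        X=X, anchors=np.arange(n, dtype=float), labels=labels,
        recording_ids=np.full(n, "r", dtype=object), window_seconds=2.0, fps=30.0,
    )


class TestTrainModel:
    def test_memorizes_small_dataset(self):
        data = tiny_dataset(10, seed=1)
        model = build_model(TINY_CFG, seed=1)
        state = train_model(
            model, data, data,
            OptimizerParams(lr=3e-3, batch_size=10, max_epochs=500, patience=500),
            seed=1,
        )
        assert min(state.train_losses) < 0.5

    def test_constant_labels_converge_to_constant_predictor(self):
        data = tiny_dataset(12, seed=2, constant_label=95.0)
        model = build_model(TINY_CFG, seed=2)
        state = train_model(
            model, data, data,
            OptimizerParams(lr=1e-3, batch_size=12, max_epochs=50, patience=50),
            seed=2,
        )
        assert state.best_val_loss < 0.2
        preds = model.predict(data.X)
        assert np.allclose(preds, 95.0, atol=0.5)

    def test_identical_seeds_give_identical_loss_curves(self):
        data = tiny_dataset(16, seed=3)
        runs = []
        for _ in range(2):
            model = build_model(TINY_CFG, seed=7)
            state = train_model(
                model, data, data,
                OptimizerParams(max_epochs=10, patience=10), seed=7,
            )
            runs.append((state.train_losses, state.val_losses))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]

    def test_checkpoint_is_lowest_validation_epoch(self):
        data = tiny_dataset(16, seed=4)
        model = build_model(TINY_CFG, seed=4)
        state = train_model(
            model, data, data, OptimizerParams(max_epochs=30, patience=30), seed=4
        )
        assert state.best_val_loss == min(state.val_losses)
        assert state.val_losses[state.best_epoch] == state.best_val_loss

    def test_empty_sets_rejected(self):
        data = tiny_dataset(4)
        with pytest.raises(ValueError):
            train_model(build_model(TINY_CFG, seed=0), data.subset([]), data)


class TestTuning:
    def test_budget_of_one_returns_single_config(self):
        data = tiny_dataset(12, seed=5)
        best, loss = tune_hyperparameters(
            {"lr": [1e-3], "dropout_p": [0.0]},
            data, data, n_configs=1, min_epochs=3,
            base_config=TINY_CFG, seed=0,
        )
        assert best == {"lr": 1e-3, "dropout_p": 0.0}

    def test_planted_good_config_beats_broken_one(self):
        data = tiny_dataset(24, seed=6)
        best, loss = tune_hyperparameters(
            {"lr": [1e-3, 10.0]},
            data, data, n_configs=6, min_epochs=4,
            base_config=TINY_CFG, seed=1,
        )
        assert best["lr"] == 1e-3

    def test_empty_space_rejected(self):
        data = tiny_dataset(8)
        with pytest.raises(ValueError):
            tune_hyperparameters({}, data, data)


class TestPostprocessing:
    def test_predictions_above_100_clipped_before_smoothing(self):
        times = np.arange(60) / 5.0
        raw = np.full(60, 101.3)
        out = postprocess(times, raw)
        assert np.all(out.post <= 100.0)
        assert np.allclose(out.post, 100.0)

    def test_constant_unchanged_by_smoothing(self):
        times = np.arange(100) / 5.0
        out = postprocess(times, np.full(100, 95.5))
        assert np.allclose(out.post, 95.5)

    def test_step_response_is_linear_ramp(self):
        # a unit step through a centered 50-sample moving average climbs
        # linearly over 50 samples
        x = np.concatenate([np.zeros(200), np.ones(200)])
        sm = moving_average(x, 50)
        mid = sm[175:225]
        assert np.all(np.diff(mid) > 0)
        ramp = np.diff(sm)
        assert np.max(ramp) == pytest.approx(1 / 50, rel=0.01)

    def test_smoothing_never_widens_range(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(88, 99, 300)
        out = postprocess(np.arange(300) / 5.0, raw)
        assert out.post.min() >= raw.min() - 1e-9
        assert out.post.max() <= raw.max() + 1e-9


class TestMetrics:
    def _traces(self, values, ref_values):
        n = len(values)
        times = np.arange(n) / 5.0
        pred = postprocess(times, np.asarray(values, float))
        pred.post = np.asarray(values, float)  # bypass smoothing for identities
        ref = SpO2Trace(times=times, values=np.asarray(ref_values, float), rate=5.0)
        return pred, ref

    def test_perfect_prediction(self):
        v = 95 + np.sin(np.arange(50) / 5)
        pred, ref = self._traces(v, v)
        rho, mae, rmse = compute_metrics(pred, ref)
        assert (rho, mae, rmse) == pytest.approx((1.0, 0.0, 0.0), abs=1e-9)

    def test_constant_offset(self):
        v = 90 + np.sin(np.arange(50) / 5)
        pred, ref = self._traces(v + 2, v)
        rho, mae, rmse = compute_metrics(pred, ref)
        assert rho == pytest.approx(1.0)
        assert mae == pytest.approx(2.0)
        assert rmse == pytest.approx(2.0)

    def test_anticorrelated_prediction(self):
        base = np.sin(np.arange(50) / 5)
        pred, ref = self._traces(95 - base, 95 + base)
        rho, _, _ = compute_metrics(pred, ref)
        assert rho == pytest.approx(-1.0)

    def test_constant_trace_yields_nan_correlation(self):
        pred, ref = self._traces(np.full(50, 95.0), 95 + np.sin(np.arange(50) / 5))
        with pytest.warns(UserWarning):
            rho, mae, rmse = compute_metrics(pred, ref)
        assert np.isnan(rho)
        assert mae <= rmse

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            v = np.clip(95 + rng.normal(0, 2, 60), 1, 100)
            r = np.clip(95 + rng.normal(0, 2, 60), 1, 100)
            pred, ref = self._traces(v, r)
            _, mae, rmse = compute_metrics(pred, ref)
            assert mae <= rmse + 1e-12


class TestGroupSummary:
    def test_median_and_iqr_convention(self):
        df = pd.DataFrame({"rho": [1.0, 2.0, 3.0, 4.0]})
        s = summarize_group(df)
        assert s.median["rho"] == pytest.approx(2.5)
        assert s.iqr["rho"] == pytest.approx(1.5)

    def test_single_value_iqr_zero(self):
        s = summarize_group(pd.DataFrame({"mae": [2.2]}))
        assert s.iqr["mae"] == 0.0

    def test_matches_sorted_quantile_oracle(self, rng):
        vals = rng.normal(0.4, 0.2, 31)
        s = summarize_group(pd.DataFrame({"rmse": vals}))
        srt = np.sort(vals)

        def quantile(q):
            pos = q * (len(srt) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(srt) - 1)
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

        assert s.median["rmse"] == pytest.approx(quantile(0.5))
        assert s.iqr["rmse"] == pytest.approx(quantile(0.75) - quantile(0.25))

    def test_nans_excluded_and_counted(self):
        df = pd.DataFrame({"rho": [0.5, np.nan, 0.7]})
        s = summarize_group(df)
        assert s.n_nan["rho"] == 1
        assert s.median["rho"] == pytest.approx(0.6)


class TestRandomGuess:
    def _reference(self, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(200.0)
        v = 95 + 3 * np.sin(t / 20) + rng.normal(0, 0.2, t.size)
        return SpO2Trace(times=t, values=np.clip(v, 1, 100), rate=1.0)

    def test_outputs_bounded_by_reference_range(self):
        ref = self._reference()
        out = random_guess_baseline(ref, seed=1)
        assert out.post.min() >= ref.values.min() - 1e-9
        assert out.post.max() <= ref.values.max() + 1e-9

    def test_deterministic_under_seed(self):
        ref = self._reference()
        a = random_guess_baseline(ref, seed=2)
        b = random_guess_baseline(ref, seed=2)
        assert np.array_equal(a.post, b.post)

    def test_constant_reference_rejected(self):
        ref = SpO2Trace(times=np.arange(30.0), values=np.full(30, 97.0))
        with pytest.raises(ValueError):
            random_guess_baseline(ref, seed=0)

    def test_median_correlation_near_zero(self):
        rhos = []
        for i in range(24):
            ref = self._reference(seed=i)
            out = random_guess_baseline(ref, seed=1000 + i)
            rho, _, _ = compute_metrics(out, ref)
            rhos.append(rho)
        assert abs(np.median(rhos)) < 0.15


class TestChannelWeights:
    def _model_with_weights(self, w):
        model = build_model(ModelConfig(variant="model1", ablation="linear_mix"), seed=0)
        model.layers[0].W[0] = np.asarray(w, dtype=float)
        return model

    def test_pure_red_weight_projection(self):
        df = extract_channel_weights([self._model_with_weights([1.0, 0.0, 0.0])])
        assert df.loc[0, ["rb_x", "rb_y"]].tolist() == pytest.approx([1.0, 0.0])
        assert df.loc[0, "ratio_br"] == 0.0
        assert df.loc[0, "ratio_gr"] == 0.0

    def test_sign_flip_maps_to_same_point(self):
        a = extract_channel_weights([self._model_with_weights([-1.0, -0.18, -0.87])])
        b = extract_channel_weights([self._model_with_weights([1.0, 0.18, 0.87])])
        assert np.allclose(
            a[["w_r", "w_g", "w_b"]].to_numpy(), b[["w_r", "w_g", "w_b"]].to_numpy()
        )

    def test_zero_norm_weight_rejected(self):
        with pytest.raises(ValueError):
            extract_channel_weights([self._model_with_weights([0.0, 0.0, 0.0])])

    def test_non_linear_mix_model_rejected(self):
        model = build_model(ModelConfig(variant="model1"), seed=0)
        with pytest.raises(ValueError):
            extract_channel_weights([model])
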