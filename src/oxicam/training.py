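"""Training loop, hyperparameter tuning, prediction traces, and metrics.

Training minimizes the root-mean-squared error of the scalar SpO2
prediction with Adam, keeping the checkpoint of the epoch with the lowest
validation loss.  Tuning is a successive-halving (HyperBand-style) search
over random configurations.  A trained model is evaluated on a recording
by predicting every 0.2-s-strided window (a 5 Hz prediction series),
clipping predictions at 100%, and smoothing with a centered 10-second
moving average; performance is summarized per recording by Pearson
correlation, MAE, and RMSE and per group by median and IQR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .models import ModelConfig, build_model
from .preprocessing import (
    SegmentScaler,
    SegmentSet,
    slide_windows,
)
from .signals import SpO2Trace
from .synthetic import SyntheticRecording

__all__ = [
    "TrainState",
    "PredictionTrace",
    "MetricsSummary",
    "TrainingDivergedError",
    "train_model",
    "tune_hyperparameters",
    "predict_trace",
    "moving_average",
    "compute_metrics",
    "summarize_group",
    "random_guess_baseline",
    "extract_channel_weights",
]

MA_SECONDS = 10.0
PRED_RATE = 5.0


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainState:
    """Outcome of one training run; checkpoint is the best-validation epoch."""

    epochs_run: int
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    best_val_loss: float
    best_checkpoint: list[np.ndarray]
    seed: int | None = None


@dataclass
class OptimizerParams:
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 30


def train_model(
    model: nn.Network,
    train: SegmentSet,
    val: SegmentSet,
    optimizer_params: OptimizerParams | None = None,
    seed: int | None = None,
) -> TrainState:
    """Fit a regressor with RMSE loss; return the lowest-validation checkpoint.

    Fully deterministic under ``seed`` (shuffling and dropout included).
    Raises :class:`TrainingDivergedError` if the loss goes non-finite.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    opt_params = optimizer_params or OptimizerParams()
    rng = np.random.default_rng(seed)
    # start the scalar head at the train-label mean: SpO2 labels live near
    # 95-100% and Adam would otherwise spend most of the epoch budget
    # closing that offset
    head = model.layers[-1]
    if isinstance(head, nn.Dense) and head.b.shape == (1,) and head.b[0] == 0.0:
        head.b[0] = float(train.labels.mean())
    optimizer = nn.Adam(model.parameters(), lr=opt_params.lr)

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_state = model.clone_state()
    since_best = 0

    for epoch in range(opt_params.max_epochs):
        order = rng.permutation(len(train))
        batch_losses = []
        for i in range(0, len(order), opt_params.batch_size):
            idx = order[i : i + opt_params.batch_size]
            pred = model.forward(train.X[idx], train=True)
            loss, grad = nn.rmse_loss(pred, train.labels[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            model.backward(grad)
            optimizer.step()
            batch_losses.append(loss)
        train_losses.append(float(np.mean(batch_losses)))

        val_pred = model.predict(val.X)
        val_loss = float(np.sqrt(np.mean((val_pred - val.labels) ** 2)))
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)
        val_losses.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.clone_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= opt_params.patience:
                break

    model.load_state(best_state)
    return TrainState(
        epochs_run=len(train_losses),
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=best_epoch,
        best_val_loss=best_val,
        best_checkpoint=best_state,
        seed=seed,
    )


def sample_config(space: dict, rng: np.random.Generator) -> dict:
    """Draw one configuration from a dict of value lists."""
    return {k: v[rng.integers(len(v))] for k, v in space.items()}


def tune_hyperparameters(
    space: dict,
    train: SegmentSet,
    val: SegmentSet,
    n_configs: int = 9,
    eta: int = 3,
    min_epochs: int = 5,
    base_config: ModelConfig | None = None,
    seed: int | None = None,
) -> tuple[dict, float]:
    """Successive-halving search over random hyperparameter configurations.

    ``space`` maps setting names (``lr``, ``kernel_size``, ``dropout_p``,
    ``batchnorm``, ``conv_filter_counts``, ``dense_widths``) to candidate
    value lists.  ``n_configs`` random draws are trained for ``min_epochs``;
    each round keeps the best ceil(n / eta) by validation RMSE and
    multiplies the epoch budget by ``eta``.  Returns (best settings, best
    validation RMSE).
    """
    if not space:
        raise ValueError("empty search space")
    if n_configs < 1:
        raise ValueError("need a budget of at least one configuration")
    rng = np.random.default_rng(seed)
    base = base_config or ModelConfig()
    candidates = [sample_config(space, rng) for _ in range(n_configs)]
    seeds = [int(rng.integers(0, 2**31 - 1)) for _ in candidates]

    budget = min_epochs
    scored: list[tuple[float, dict]] = []
    while candidates:
        scored = []
        for cand, s in zip(candidates, seeds):
            cfg_kwargs = {k: v for k, v in cand.items() if k != "lr"}
            cfg = ModelConfig(**{**base.to_dict(), **cfg_kwargs})
            model = build_model(cfg, seed=s)
            opt = OptimizerParams(
                lr=cand.get("lr", 1e-3), max_epochs=budget, patience=budget
            )
            try:
                state = train_model(model, train, val, opt, seed=s)
                scored.append((state.best_val_loss, cand))
            except TrainingDivergedError:
                scored.append((np.inf, cand))
        scored.sort(key=lambda t: t[0])
        keep = int(np.ceil(len(scored) / eta))
        if keep == len(scored):
            break
        kept = scored[:keep]
        candidates = [c for _, c in kept]
        seeds = seeds[: len(candidates)]
        budget *= eta
        if len(candidates) == 1:
            break
    best_loss, best = min(scored, key=lambda t: t[0])
    return best, float(best_loss)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window=window, center=True, min_periods=1).mean().to_numpy()


@dataclass
class PredictionTrace:
    """A 5 Hz prediction series: raw and postprocessed (clipped, smoothed)."""

    times: np.ndarray
    raw: np.ndarray
    post: np.ndarray
    model_id: str = ""

    def as_trace(self) -> SpO2Trace:
        return SpO2Trace(times=self.times, values=self.post, rate=PRED_RATE)


def postprocess(times: np.ndarray, raw: np.ndarray, model_id: str = "") -> PredictionTrace:
    """Clip raw predictions at 100% then apply the 10-s moving average."""
    clipped = np.minimum(np.asarray(raw, dtype=float), 100.0)
    window = int(round(MA_SECONDS * PRED_RATE))
    post = moving_average(clipped, window)
    return PredictionTrace(times=np.asarray(times, float), raw=np.asarray(raw, float),
                           post=post, model_id=model_id)


def predict_trace(
    model: nn.Network,
    recording: SyntheticRecording,
    scaler: SegmentScaler,
    model_id: str = "",
) -> PredictionTrace:
    """Sequentially predict every window of a recording and postprocess."""
    segs = slide_windows(recording.signal, recording_id=recording.recording_id)
    if len(segs) == 0:
        raise ValueError("recording shorter than one window")
    X = scaler.transform(segs).X
    raw = model.predict(X)
    return postprocess(segs.anchors, raw, model_id=model_id or model.name)


def compute_metrics(
    prediction: PredictionTrace, reference: SpO2Trace
) -> tuple[float, float, float]:
    """(Pearson rho, MAE, RMSE) over the overlap of the 5 Hz grids.

    A constant prediction or reference makes the correlation undefined;
    NaN is returned for rho with a warning.
    """
    lo = max(prediction.times[0], reference.times[0])
    hi = min(prediction.times[-1], reference.times[-1])
    if hi <= lo:
        raise ValueError("prediction and reference do not overlap in time")
    keep = (prediction.times >= lo - 1e-9) & (prediction.times <= hi + 1e-9)
    t = prediction.times[keep]
    p = prediction.post[keep]
    r = np.interp(t, reference.times, reference.values)
    err = p - r
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.ptp(p) < 1e-12 or np.ptp(r) < 1e-12:
        warnings.warn("constant trace: Pearson correlation undefined (NaN)")
        return np.nan, mae, rmse
    rho = float(stats.pearsonr(p, r).statistic)
    return rho, mae, rmse


@dataclass
class MetricsSummary:
    """Group summary: median and IQR of per-recording rho, MAE, RMSE."""

    per_recording: pd.DataFrame
    median: dict[str, float] = field(default_factory=dict)
    iqr: dict[str, float] = field(default_factory=dict)
    n_nan: dict[str, int] = field(default_factory=dict)


def summarize_group(per_recording: pd.DataFrame) -> MetricsSummary:
    """Median and IQR (Q3 - Q1, linear-interpolation quantiles) per metric.

    NaNs (undefined correlations) are excluded with their count reported.
    """
    if len(per_recording) == 0:
        raise ValueError("no recordings to summarize")
    median, iqr, n_nan = {}, {}, {}
    for col in ("rho", "mae", "rmse"):
        if col not in per_recording:
            continue
        vals = per_recording[col].to_numpy(float)
        n_nan[col] = int(np.sum(np.isnan(vals)))
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"metric {col} is NaN for every recording")
        median[col] = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
        iqr[col] = float(q3 - q1)
    return MetricsSummary(per_recording=per_recording, median=median, iqr=iqr, n_nan=n_nan)


def random_guess_baseline(reference: SpO2Trace, seed: int | None = None) -> PredictionTrace:
    """Null predictor: uniform draws in [min, max] of the reference, smoothed.

    Values are drawn i.i.d. at 5 Hz over the reference span and passed
    through the same 10-s moving average as real predictions.
    """
    lo = float(reference.values.min())
    hi = float(reference.values.max())
    if hi - lo < 1e-12:
        raise ValueError("constant reference: random-guess correlation undefined")
    rng = np.random.default_rng(seed)
    t0, t1 = reference.span
    n = int(np.floor((t1 - t0) * PRED_RATE)) + 1
    times = t0 + np.arange(n) / PRED_RATE
    raw = rng.uniform(lo, hi, size=n)
    return postprocess(times, raw, model_id="random_guess")


def extract_channel_weights(
    models: list[nn.Network], test_rhos: list[float] | None = None
) -> pd.DataFrame:
    """First-layer RGB weight directions of linear-mix model instances.

    Each model must start with a single-output channel combination layer.
    Weight vectors are normalized to unit norm with a nonnegative red
    component (a linear layer followed by the rest of the network is
    invariant to this scale/sign choice).  Returns a DataFrame with the
    normalized components, RB / RG plane projections, blue/red and
    green/red weight ratios, and the instance's test correlation tag.
    """
    rows = []
    test_rhos = test_rhos if test_rhos is not None else [np.nan] * len(models)
    for model, rho in zip(models, test_rhos):
        first = model.layers[0]
        if not isinstance(first, nn.ChannelMix) or first.W.shape[0] != 1:
            raise ValueError("model must start with a single-output channel mix layer")
        w = first.W[0].astype(float)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("zero-norm weight vector")
        w = w / norm
        if w[0] < 0:
            w = -w
        rows.append(
            {
                "w_r": w[0], "w_g": w[1], "w_b": w[2],
                "rb_x": w[0], "rb_y": w[2],
                "rg_x": w[0], "rg_y": w[1],
                "ratio_br": w[2] / w[0] if w[0] != 0 else np.inf,
                "ratio_gr": w[1] / w[0] if w[0] != 0 else np.inf,
                "test_rho": rho,
            }
        )
    return pd.DataFrame(rows)
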