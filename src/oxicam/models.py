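"""SpO2 regressors: channel-combination CNNs and the ratio-of-ratios baseline.

Three optophysiology-inspired architectures map a standardized 3 x 300
segment of skin color signal to a scalar SpO2:

* **model1** — channel mixing first: stacked channel combination layers
  (3 -> 16 -> 12 -> 7 channels) followed by conv + max-pool temporal
  feature extraction and a dense head (~3e4 parameters).
* **model2** — features first: an independent conv + max-pool stack per
  color channel (no weight sharing across channels), then channel
  combination layers on the pooled features and a dense head (~1e4).
* **model3** — interleaved: conv layers with decreasing filter counts mix
  channels implicitly while pooling downsamples time (~3e5).

Ablation variants of model1 replace the nonlinear mixing stack with a
single linear channel combination layer (``linear_mix`` — also the variant
whose first-layer weights are visualized), or the convolutional feature
extractor with dense layers (``dense_features``).

The classical baseline estimates SpO2 = a - b * RR from the ratio-of-ratios
RR = (AC/DC)_red / (AC/DC)_blue, with (a, b) fitted by least squares.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from . import nn
from .preprocessing import SegmentSet

__all__ = [
    "ModelConfig",
    "ChannelCombinationLayer",
    "channel_combination_forward",
    "build_model",
    "compute_ac_dc",
    "ratio_of_ratios",
    "RatioOfRatiosCalibration",
    "fit_ror_calibration",
    "ror_predict",
    "export_channel_layer",
]

PULSE_BAND = (0.5, 4.0)  # Hz, covers 30-240 bpm

# alias: the channel combination layer is the nn.ChannelMix primitive
ChannelCombinationLayer = nn.ChannelMix


def channel_combination_forward(
    U: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """Single channel-combination forward pass V = act(W U + b 1^T).

    ``U`` is Cin x L, ``W`` Cout x Cin, ``b`` length Cout.  Functional
    counterpart of :class:`ChannelCombinationLayer` for one segment.
    """
    U = np.asarray(U, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if U.ndim != 2 or W.ndim != 2 or W.shape[1] != U.shape[0] or b.shape != (W.shape[0],):
        raise ValueError(
            f"dimension mismatch: U {U.shape}, W {W.shape}, b {b.shape}"
        )
    V = W @ U + b[:, None]
    if activation == "relu":
        return np.maximum(V, 0.0)
    if activation == "identity":
        return V
    raise ValueError(f"unknown activation {activation!r}")


@dataclass
class ModelConfig:
    """Architecture and regularization settings for one regressor variant."""

    variant: str = "model1"  # model1 | model2 | model3
    channel_layer_widths: tuple[int, ...] = (16, 12, 7)
    conv_filter_counts: tuple[int, ...] | None = None
    kernel_size: int = 7
    pool_factor: int = 2
    dropout_p: float = 0.0
    batchnorm: bool = False
    dense_widths: tuple[int, ...] | None = None
    ablation: str = "none"  # none | linear_mix | dense_features
    input_len: int = 300
    input_channels: int = 3

    def __post_init__(self) -> None:
        if self.variant not in ("model1", "model2", "model3"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.ablation not in ("none", "linear_mix", "dense_features"):
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.variant == "model1" and self.ablation == "none":
            if len(self.channel_layer_widths) < 3 or self.channel_layer_widths[-1] != 7:
                raise ValueError(
                    "model1 requires >= 3 channel combination layers ending at 7 channels"
                )
        if self.conv_filter_counts is None:
            self.conv_filter_counts = {
                "model1": (16, 8, 4),
                "model2": (8, 4),
                "model3": (64, 32, 16, 8),
            }[self.variant]
        if self.dense_widths is None:
            self.dense_widths = {
                "model1": (200,),
                "model2": (20,),
                "model3": (2000,),
            }[self.variant]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("channel_layer_widths", "conv_filter_counts", "dense_widths"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _conv_block(c_in, filters, k, pool, cfg, rng) -> tuple[list[nn.Layer], int]:
    layers: list[nn.Layer] = [nn.Conv1d(c_in, filters, k, rng)]
    if cfg.batchnorm:
        layers.append(nn.BatchNorm1d(filters))
    layers.append(nn.ReLU())
    layers.append(nn.MaxPool1d(pool))
    return layers, filters


def _head(n_in, cfg, rng) -> list[nn.Layer]:
    layers: list[nn.Layer] = [nn.Flatten()]
    width = n_in
    for w in cfg.dense_widths:
        layers.append(nn.Dense(width, w, rng))
        layers.append(nn.ReLU())
        if cfg.dropout_p > 0:
            layers.append(nn.Dropout(cfg.dropout_p, rng))
        width = w
    layers.append(nn.Dense(width, 1, rng))
    return layers


def build_model(config: ModelConfig, seed: int | None = None) -> nn.Network:
    """Instantiate a regressor variant as a :class:`oxicam.nn.Network`."""
    cfg = config
    rng = np.random.default_rng(seed)
    L = cfg.input_len
    layers: list[nn.Layer] = []

    if cfg.variant == "model1":
        if cfg.ablation == "linear_mix":
            # single linear channel combination, no activation
            layers.append(nn.ChannelMix(cfg.input_channels, 1, rng, activation="identity"))
            c = 1
        else:
            c = cfg.input_channels
            for w in cfg.channel_layer_widths:
                layers.append(nn.ChannelMix(c, w, rng, activation="relu"))
                c = w
        if cfg.ablation == "dense_features":
            layers.append(nn.Flatten())
            width = c * L
            for w in (64, 32):
                layers.append(nn.Dense(width, w, rng))
                layers.append(nn.ReLU())
                width = w
            layers.append(nn.Dense(width, 1, rng))
            return nn.Network(layers, name=f"{cfg.variant}:{cfg.ablation}")
        for f in cfg.conv_filter_counts:
            block, c = _conv_block(c, f, cfg.kernel_size, cfg.pool_factor, cfg, rng)
            layers.extend(block)
            L //= cfg.pool_factor
        layers.extend(_head(c * L, cfg, rng))

    elif cfg.variant == "model2":
        stacks = []
        Lc = L
        for _ in range(cfg.input_channels):
            sub: list[nn.Layer] = []
            Lc = L
            c = 1
            for f in cfg.conv_filter_counts:
                block, c = _conv_block(c, f, cfg.kernel_size, cfg.pool_factor, cfg, rng)
                sub.extend(block)
                Lc //= cfg.pool_factor
            stacks.append(sub)
        layers.append(nn.PerChannelStack(stacks))
        c = cfg.conv_filter_counts[-1] * cfg.input_channels
        for w in (10, 8, 7):
            layers.append(nn.ChannelMix(c, w, rng, activation="relu"))
            c = w
        layers.extend(_head(c * Lc, cfg, rng))

    else:  # model3
        c = cfg.input_channels
        for f in cfg.conv_filter_counts:
            block, c = _conv_block(c, f, cfg.kernel_size, cfg.pool_factor, cfg, rng)
            layers.extend(block)
            L //= cfg.pool_factor
        layers.extend(_head(c * L, cfg, rng))

    if L < 1:
        raise ValueError("pooling collapsed the time axis; check widths vs input_len")
    return nn.Network(layers, name=f"{cfg.variant}:{cfg.ablation}")


def compute_ac_dc(
    window: np.ndarray, fps: float, band: tuple[float, float] = PULSE_BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (AC, DC) of a raw signal window.

    DC is the window mean; AC is sqrt(2) x RMS of the band-passed cardiac
    component (0.5-4 Hz by default), i.e. the amplitude of an equivalent
    sinusoid.  The window must be at least 5 s long.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n = window.shape[1]
    if n < 5 * fps:
        raise ValueError("window must be at least 5 seconds long")
    dc = window.mean(axis=1)
    if np.any(dc <= 0):
        raise ValueError("non-positive DC component")
    nyq = fps / 2.0
    b, a = butter(3, [band[0] / nyq, band[1] / nyq], btype="band")
    ac_part = filtfilt(b, a, window - dc[:, None], axis=1)
    ac = np.sqrt(2.0) * np.sqrt(np.mean(ac_part**2, axis=1))
    return ac, dc


def ratio_of_ratios(
    window: np.ndarray,
    fps: float,
    channel_pair: tuple[int, int] = (0, 2),
    band: tuple[float, float] = PULSE_BAND,
) -> float:
    """RR = (AC/DC)_numerator / (AC/DC)_denominator for one raw window."""
    ac, dc = compute_ac_dc(window, fps, band)
    num, den = channel_pair
    r_num = ac[num] / dc[num]
    r_den = ac[den] / dc[den]
    if r_den <= 0:
        raise ValueError("denominator channel has zero AC component")
    return float(r_num / r_den)


@dataclass
class RatioOfRatiosCalibration:
    """Affine calibration SpO2 = a - b * RR (prediction clipped to (0, 100])."""

    a: float
    b: float
    channel_pair: tuple[int, int] = (0, 2)  # (red, blue)
    band: tuple[float, float] = PULSE_BAND

    def predict_rr(self, rr) -> np.ndarray:
        pred = self.a - self.b * np.asarray(rr, dtype=float)
        return np.clip(pred, 1e-6, 100.0)


def fit_ror_calibration(
    segments: SegmentSet,
    channel_pair: tuple[int, int] = (0, 2),
    band: tuple[float, float] = PULSE_BAND,
) -> RatioOfRatiosCalibration:
    """Least-squares fit of SpO2 = a - b * RR over labeled raw windows."""
    if len(segments) < 2:
        raise ValueError("need at least 2 windows to fit a calibration")
    rr = np.array(
        [ratio_of_ratios(x, segments.fps, channel_pair, band) for x in segments.X]
    )
    y = segments.labels
    if np.any(np.isnan(y)):
        raise ValueError("windows must be labeled")
    if np.ptp(rr) < 1e-12:
        if np.ptp(y) < 1e-12:
            return RatioOfRatiosCalibration(a=float(y[0]), b=0.0,
                                            channel_pair=channel_pair, band=band)
        raise ValueError("rank-deficient design: all RR values identical")
    design = np.column_stack([np.ones_like(rr), -rr])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return RatioOfRatiosCalibration(
        a=float(coef[0]), b=float(coef[1]), channel_pair=channel_pair, band=band
    )


def ror_predict(
    calibration: RatioOfRatiosCalibration, window: np.ndarray, fps: float
) -> float:
    """Predict SpO2 for one raw window from a fitted calibration."""
    rr = ratio_of_ratios(window, fps, calibration.channel_pair, calibration.band)
    return float(calibration.predict_rr(rr))


def export_channel_layer(model: nn.Network) -> dict:
    """Framework-neutral export of the first channel-combination layer.

    Returns ``{"W": ..., "b": ..., "activation": ...}`` with plain lists,
    suitable for JSON serialization and the weight-visualization tooling.
    """
    for layer in model.layers:
        if isinstance(layer, nn.ChannelMix):
            return {
                "W": layer.W.tolist(),
                "b": layer.b.tolist(),
                "activation": layer.activation,
            }
    raise ValueError("model contains no channel combination layer")
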