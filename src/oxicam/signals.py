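"""Core time-series containers shared across the pipeline.

Two objects circulate through every stage:

* :class:`SkinColorSignal` — the per-frame spatial means of the R, G, B
  values of skin pixels ("skin color signal"), a 3 x T matrix at the video
  frame rate.
* :class:`SpO2Trace` — a time-stamped sequence of blood oxygen saturation
  percentages, either a reference measurement (1 Hz pulse oximeter) or a
  model prediction (5 Hz).

Both round-trip through plain CSV so that recordings can be inspected and
exchanged without any binary dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SkinColorSignal", "SpO2Trace"]

CHANNELS = ("R", "G", "B")
RED, GREEN, BLUE = 0, 1, 2


@dataclass
class SkinColorSignal:
    """Spatially averaged skin-pixel intensities, one column per frame.

    Parameters
    ----------
    values
        Array of shape ``(3, T)`` with rows R, G, B on the 0-255 scale.
    fps
        Video frame rate in frames per second (> 0).
    """

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ValueError(f"values must be 3xT, got shape {self.values.shape}")
        if self.values.shape[1] < 1:
            raise ValueError("signal must contain at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds (T / fps)."""
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame k at k / fps)."""
        return np.arange(self.n_frames) / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, **{c: self.values[i] for i, c in enumerate(CHANNELS)}}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SkinColorSignal":
        df = pd.read_csv(path)
        values = np.vstack([df[c].to_numpy(float) for c in CHANNELS])
        t = df["time_s"].to_numpy(float)
        if len(t) > 1:
            fps = 1.0 / np.median(np.diff(t))
        else:
            fps = 30.0
        return cls(values=values, fps=float(fps))


@dataclass
class SpO2Trace:
    """Time-stamped SpO2 percentages.

    ``times`` are strictly increasing seconds; ``values`` lie in (0, 100];
    ``rate`` is the nominal sampling rate in Hz (1 Hz for a pulse-oximeter
    reference, 5 Hz for interpolated references and model predictions).
    """

    times: np.ndarray
    values: np.ndarray
    rate: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if np.any(self.values <= 0) or np.any(self.values > 100):
            raise ValueError("SpO2 values must lie in (0, 100]")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def at(self, t) -> np.ndarray:
        """Linearly interpolated value(s) at time(s) ``t`` (within the span)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.span
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(f"query time outside reference span [{lo}, {hi}]")
        return np.interp(t, self.times, self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "spo2": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rate: float | None = None) -> "SpO2Trace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if rate is None:
            rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
        return cls(times=t, values=df["spo2"].to_numpy(float), rate=float(rate))
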