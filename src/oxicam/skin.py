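"""Skin segmentation and skin color signal extraction.

Skin pixels are separated from the background along the Cr (red-chroma)
axis of the YCbCr color space: skin chroma is red-shifted relative to
typical backgrounds, so a single Otsu threshold on the Cr histogram splits
each frame into a low-Cr background class and a high-Cr skin class.  The
R, G, B values of the skin pixels are spatially averaged per frame to form
the skin color signal.

The YCbCr conversion uses the full-range BT.601 (JPEG) matrix; the dialect
is centralized in :data:`YCBCR_MATRIX` / :data:`YCBCR_OFFSET` so a single
constant switch changes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signals import SkinColorSignal

__all__ = [
    "FrameSequence",
    "SkinMask",
    "DegenerateHistogramError",
    "rgb_to_ycbcr",
    "otsu_threshold",
    "segment_skin_mask",
    "extract_skin_color_signal",
    "load_frame_directory",
]

# Full-range BT.601 (JPEG) RGB -> YCbCr.  Rows: Y, Cb, Cr.
YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])

SKIN_FRACTION_BAND = (0.02, 0.98)


class DegenerateHistogramError(ValueError):
    """Raised when Otsu thresholding is attempted on a single-valued input."""


@dataclass
class FrameSequence:
    """A stack of same-shape RGB frames with a frame rate."""

    frames: np.ndarray  # (T, H, W, 3), values in [0, 255]
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class SkinMask:
    mask: np.ndarray  # boolean (H, W)
    skin_fraction: float
    threshold: float
    plausible: bool  # skin_fraction inside SKIN_FRACTION_BAND

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def rgb_to_ycbcr(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame (H x W x 3 or N x 3, 0-255) to full-range YCbCr.

    Neutral grays map to Cb = Cr = 128; outputs are clipped to [0, 255].
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-1] != 3:
        raise ValueError("last axis must hold 3 channels (R, G, B)")
    ycbcr = frame @ YCBCR_MATRIX.T + YCBCR_OFFSET
    return np.clip(ycbcr, 0.0, 255.0)


def otsu_threshold(counts: np.ndarray, bin_values: np.ndarray | None = None) -> float:
    """Otsu's threshold from a histogram: minimize within-class variance.

    ``counts[i]`` is the number of pixels with value ``bin_values[i]``
    (default ``0..len(counts)-1``).  The returned threshold t puts bins with
    value <= t in the lower class.  Every candidate cut is evaluated
    exhaustively; ties are broken toward the lowest qualifying bin.
    """
    counts = np.asarray(counts, dtype=float)
    if bin_values is None:
        bin_values = np.arange(counts.size, dtype=float)
    bin_values = np.asarray(bin_values, dtype=float)
    populated = counts > 0
    if populated.sum() < 2:
        raise DegenerateHistogramError("histogram has fewer than 2 populated bins")

    w = counts / counts.sum()
    # cumulative moments for class 0 = bins [0..k], class 1 = bins [k+1..]
    w0 = np.cumsum(w)
    mu_cum = np.cumsum(w * bin_values)
    mu_total = mu_cum[-1]
    sq_cum = np.cumsum(w * bin_values**2)
    sq_total = sq_cum[-1]

    k = np.arange(counts.size - 1)
    w1 = 1.0 - w0[k]
    valid = (w0[k] > 0) & (w1 > 0)
    mu0 = np.where(w0[k] > 0, mu_cum[k] / np.maximum(w0[k], 1e-300), 0.0)
    mu1 = np.where(w1 > 0, (mu_total - mu_cum[k]) / np.maximum(w1, 1e-300), 0.0)
    var0 = sq_cum[k] / np.maximum(w0[k], 1e-300) - mu0**2
    var1 = (sq_total - sq_cum[k]) / np.maximum(w1, 1e-300) - mu1**2
    within = w0[k] * var0 + w1 * var1
    within[~valid] = np.inf
    # tie-break toward the lowest qualifying bin, tolerant of fp rounding
    m = within.min()
    tol = 1e-10 * max(1.0, abs(m))
    best = int(np.argmax(within <= m + tol))
    return float(bin_values[best])


def _cr_histogram(cr: np.ndarray) -> np.ndarray:
    return np.bincount(np.clip(np.round(cr).astype(int), 0, 255).ravel(), minlength=256)


def segment_skin_mask(frame: np.ndarray) -> SkinMask:
    """Segment skin pixels of one frame by Otsu-thresholding the Cr channel.

    The skin class is the Otsu class with the higher mean Cr.  A
    ``plausible`` flag marks skin fractions outside [0.02, 0.98], which
    usually indicates a frame without a discernible hand.
    """
    cr = rgb_to_ycbcr(frame)[..., 2]
    thr = otsu_threshold(_cr_histogram(cr))
    # compare on the same rounded scale the histogram was built from
    lower = np.round(cr) <= thr
    upper = ~lower
    # pick the class with higher mean Cr as skin
    mean_low = cr[lower].mean() if lower.any() else -np.inf
    mean_high = cr[upper].mean() if upper.any() else -np.inf
    mask = upper if mean_high >= mean_low else lower
    frac = float(mask.mean())
    plausible = SKIN_FRACTION_BAND[0] <= frac <= SKIN_FRACTION_BAND[1]
    return SkinMask(mask=mask, skin_fraction=frac, threshold=thr, plausible=plausible)


def extract_skin_color_signal(
    frames: FrameSequence, per_frame_threshold: bool = True
) -> SkinColorSignal:
    """Spatially average skin pixels of every frame into the 3 x T signal.

    With ``per_frame_threshold`` (default) the Otsu threshold is recomputed
    per frame, which is robust to lighting drift; otherwise the first
    frame's threshold and class orientation are reused for the whole clip.
    """
    stack = frames.frames
    values = np.empty((3, len(frames)))
    fixed_thr: float | None = None
    skin_is_upper = True
    for t in range(len(frames)):
        if per_frame_threshold or fixed_thr is None:
            sm = segment_skin_mask(stack[t])
            if not per_frame_threshold:
                fixed_thr = sm.threshold
                cr0 = np.round(rgb_to_ycbcr(stack[t])[..., 2])
                skin_is_upper = bool(np.array_equal(sm.mask, cr0 > sm.threshold))
            mask = sm.mask
        else:
            cr = np.round(rgb_to_ycbcr(stack[t])[..., 2])
            upper = cr > fixed_thr
            mask = upper if skin_is_upper else ~upper
        if not mask.any():
            raise ValueError(f"frame {t}: empty skin mask")
        values[:, t] = stack[t][mask].mean(axis=0)
    return SkinColorSignal(values=values, fps=frames.fps)


def load_frame_directory(path, fps: float = 30.0) -> FrameSequence:
    """Load a directory of numbered PNG frames into a :class:`FrameSequence`."""
    import imageio.v3 as iio

    files = sorted(Path(path).glob("*.png"))
    if not files:
        raise FileNotFoundError(f"no PNG frames under {path}")
    frames = np.stack([np.asarray(iio.imread(f), dtype=float)[..., :3] for f in files])
    return FrameSequence(frames=frames, fps=fps)
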