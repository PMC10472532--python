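"""Windowing, reference alignment, standardization, balancing, and splits.

The skin color signal is cut into 10-second segments with a 0.2-second
stride (5 segments per second of video; 3 x 300 samples at 30 fps).  The
1 Hz reference SpO2 is resampled to 5 Hz with a smoothing spline so every
segment can be paired with a reference value, forming the (U, SpO2)
training pairs.  Standardization uses train-set per-channel statistics
only, oversampling balances the heavily skewed SpO2 label distribution,
and split plans keep train/validation/test segments structurally disjoint
(breath cycles within a recording for train/validation, whole recordings
or whole participants for test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .signals import SkinColorSignal, SpO2Trace
from .synthetic import SyntheticRecording

__all__ = [
    "SegmentSet",
    "SegmentScaler",
    "SplitPlan",
    "slide_windows",
    "interpolate_reference",
    "label_segments",
    "standardize_segments",
    "oversample_balanced",
    "make_split",
    "segments_in_interval",
]

WINDOW_SECONDS = 10.0
STRIDE_SECONDS = 0.2
TARGET_RATE = 5.0


@dataclass
class SegmentSet:
    """A batch of input segments U (N x 3 x L) with labels and anchors.

    ``anchors`` holds each segment's anchor time in seconds (window end by
    default — causal, matching live monitoring; window center if the set
    was built with ``anchor='center'``).  ``labels`` is NaN until
    :func:`label_segments` pairs the windows with a reference.
    """

    X: np.ndarray
    anchors: np.ndarray
    labels: np.ndarray
    recording_ids: np.ndarray
    window_seconds: float = WINDOW_SECONDS
    fps: float = 30.0
    anchor_mode: str = "end"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.anchors = np.asarray(self.anchors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.recording_ids = np.asarray(self.recording_ids)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "SegmentSet":
        return SegmentSet(
            X=self.X[idx],
            anchors=self.anchors[idx],
            labels=self.labels[idx],
            recording_ids=self.recording_ids[idx],
            window_seconds=self.window_seconds,
            fps=self.fps,
            anchor_mode=self.anchor_mode,
        )

    @staticmethod
    def concatenate(sets: list["SegmentSet"]) -> "SegmentSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        return SegmentSet(
            X=np.concatenate([s.X for s in sets]),
            anchors=np.concatenate([s.anchors for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            recording_ids=np.concatenate([s.recording_ids for s in sets]),
            window_seconds=sets[0].window_seconds,
            fps=sets[0].fps,
            anchor_mode=sets[0].anchor_mode,
        )

    def save(self, path) -> None:
        """Archive the set as a compressed NPZ (metadata in the archive)."""
        np.savez_compressed(
            path,
            X=self.X,
            anchors=self.anchors,
            labels=self.labels,
            recording_ids=self.recording_ids.astype(str),
            meta=np.array(
                [self.window_seconds, self.fps], dtype=float
            ),
            anchor_mode=np.array(self.anchor_mode),
        )

    @classmethod
    def load(cls, path) -> "SegmentSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                X=z["X"],
                anchors=z["anchors"],
                labels=z["labels"],
                recording_ids=z["recording_ids"].astype(object),
                window_seconds=float(z["meta"][0]),
                fps=float(z["meta"][1]),
                anchor_mode=str(z["anchor_mode"]),
            )


def slide_windows(
    signal: SkinColorSignal,
    window_s: float = WINDOW_SECONDS,
    stride_s: float = STRIDE_SECONDS,
    recording_id: str = "",
    anchor: str = "end",
) -> SegmentSet:
    """Cut a signal into overlapping 3 x L windows.

    L = round(window_s * fps); segment count is floor((T - L) / stride) + 1.
    A signal shorter than one window yields an empty set with a warning.
    """
    if anchor not in ("end", "center"):
        raise ValueError("anchor must be 'end' or 'center'")
    L = int(round(window_s * signal.fps))
    stride = max(1, int(round(stride_s * signal.fps)))
    T = signal.n_frames
    if T < L:
        warnings.warn("signal shorter than one window; returning empty segment set")
        return SegmentSet(
            X=np.empty((0, 3, L)),
            anchors=np.empty(0),
            labels=np.empty(0),
            recording_ids=np.empty(0, dtype=object),
            window_seconds=window_s,
            fps=signal.fps,
            anchor_mode=anchor,
        )
    n = (T - L) // stride + 1
    starts = np.arange(n) * stride
    X = np.stack([signal.values[:, s : s + L] for s in starts])
    ends = (starts + L) / signal.fps
    anchors = ends if anchor == "end" else ends - window_s / 2.0
    return SegmentSet(
        X=X,
        anchors=anchors,
        labels=np.full(n, np.nan),
        recording_ids=np.full(n, recording_id, dtype=object),
        window_seconds=window_s,
        fps=signal.fps,
        anchor_mode=anchor,
    )


def interpolate_reference(trace: SpO2Trace, target_rate: float = TARGET_RATE) -> SpO2Trace:
    """Resample a reference trace with a GCV smoothing spline.

    The 1 Hz pulse-oximeter reference is resampled to ``target_rate``
    (default 5 Hz, the segment rate at a 0.2 s stride) within its original
    time span; the smoothing parameter is chosen by generalized
    cross-validation.  Outputs are clipped to (0, 100].
    """
    if len(trace) < 4:
        raise ValueError("need at least 4 reference points for spline resampling")
    spline = make_smoothing_spline(trace.times, trace.values)
    t0, t1 = trace.span
    n = int(np.floor((t1 - t0) * target_rate)) + 1
    times = t0 + np.arange(n) / target_rate
    values = np.clip(spline(times), 1e-6, 100.0)
    return SpO2Trace(times=times, values=values, rate=target_rate, meta=dict(trace.meta))


def label_segments(
    segments: SegmentSet, reference: SpO2Trace, mode: str = "anchor"
) -> SegmentSet:
    """Pair every window with a reference SpO2 value.

    ``mode='anchor'`` (default) takes the reference at the window's anchor
    time — the convention for the CNN pipeline.  ``mode='window_mean'``
    averages the reference over the window's time extent, the natural
    target for window statistics such as the AC/DC ratio-of-ratios, which
    measure the average modulation over the whole window.
    """
    out = segments.subset(slice(None))
    if mode == "anchor":
        labels = reference.at(segments.anchors)  # raises if anchor outside span
    elif mode == "window_mean":
        lo, hi = reference.span
        w = segments.window_seconds
        labels = []
        for a in segments.anchors:
            if segments.anchor_mode == "center":
                t0, t1 = a - w / 2.0, a + w / 2.0
            else:
                t0, t1 = a - w, a
            tt = np.linspace(max(t0, lo), min(t1, hi), 51)
            labels.append(float(reference.at(tt).mean()))
    else:
        raise ValueError(f"unknown labeling mode {mode!r}")
    out.labels = np.asarray(labels, dtype=float)
    return out


@dataclass
class SegmentScaler:
    """Per-channel standardization fitted on training data only."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    std: np.ndarray = field(default_factory=lambda: np.ones(3))

    def fit(self, segments: SegmentSet) -> "SegmentScaler":
        if len(segments) == 0:
            raise ValueError("cannot fit scaler on an empty segment set")
        self.mean = segments.X.mean(axis=(0, 2))
        self.std = segments.X.std(axis=(0, 2))
        if np.any(self.std == 0):
            raise ValueError("zero variance in a channel of the training data")
        return self

    def transform(self, segments: SegmentSet) -> SegmentSet:
        out = segments.subset(slice(None))
        out.X = (segments.X - self.mean[None, :, None]) / self.std[None, :, None]
        return out

    def inverse_transform(self, segments: SegmentSet) -> SegmentSet:
        out = segments.subset(slice(None))
        out.X = segments.X * self.std[None, :, None] + self.mean[None, :, None]
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentScaler":
        return cls(mean=np.asarray(d["mean"], float), std=np.asarray(d["std"], float))


def standardize_segments(
    train: SegmentSet, *others: SegmentSet
) -> tuple[list[SegmentSet], SegmentScaler]:
    """Standardize every set with per-channel statistics of ``train`` only."""
    scaler = SegmentScaler().fit(train)
    out = [scaler.transform(train)] + [scaler.transform(s) for s in others]
    return out, scaler


def oversample_balanced(
    segments: SegmentSet, n_out: int, seed: int | None = None, bin_width: float = 1.0
) -> SegmentSet:
    """Sample ``n_out`` segments with replacement, flattening the label histogram.

    Each segment is weighted inversely to the population of its SpO2 label
    bin (``bin_width`` percent wide), which counteracts the strong skew of
    breath-protocol labels toward the normal range.
    """
    if len(segments) == 0:
        raise ValueError("empty segment set")
    if n_out <= 0:
        raise ValueError("n_out must be positive")
    labels = segments.labels
    if np.any(np.isnan(labels)):
        raise ValueError("segments must be labeled before oversampling")
    bins = np.floor(labels / bin_width).astype(int)
    _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    weights = 1.0 / counts[inverse]
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(segments), size=n_out, replace=True, p=weights)
    return segments.subset(idx)


@dataclass
class SplitPlan:
    """Recording/cycle-level train/validation/test assignment.

    ``train`` and ``val`` map recording ids to lists of (t_lo, t_hi) time
    intervals; windows are assigned to a role only if the whole window lies
    inside one of the role's intervals, so train and validation can never
    share overlapping segments.  ``test`` lists whole recording ids.
    """

    mode: str
    train: dict[str, list[tuple[float, float]]]
    val: dict[str, list[tuple[float, float]]]
    test: list[str]
    held_out_subject: str | None = None
    cv_groups: list[list[str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "train": self.train,
            "val": self.val,
            "test": self.test,
            "held_out_subject": self.held_out_subject,
            "cv_groups": self.cv_groups,
        }


def segments_in_interval(
    segments: SegmentSet, intervals: list[tuple[float, float]]
) -> np.ndarray:
    """Boolean index of windows lying entirely inside one of the intervals."""
    if segments.anchor_mode == "center":
        starts = segments.anchors - segments.window_seconds / 2.0
        ends = segments.anchors + segments.window_seconds / 2.0
    else:  # end-anchored windows span [anchor - window, anchor]
        starts = segments.anchors - segments.window_seconds
        ends = segments.anchors
    keep = np.zeros(len(segments), dtype=bool)
    for lo, hi in intervals:
        keep |= (starts >= lo - 1e-9) & (ends <= hi + 1e-9)
    return keep


def make_split(
    recordings: list[SyntheticRecording],
    mode: str = "participant_specific",
    held_out: str | None = None,
    position: str | None = None,
) -> SplitPlan:
    """Build a split plan over a cohort of recordings.

    ``participant_specific``: for each subject (and hand position), cycles
    1-2 of session 1 train, cycle 3 of session 1 validates, session 2 is
    the test recording.  ``leave_one_out``: every recording of ``held_out``
    is test; the remaining subjects form participant-wise cross-validation
    groups.
    """
    recs = [r for r in recordings if position is None or r.hand_position == position]
    if not recs:
        raise ValueError("no recordings to split")
    for r in recs:
        if not r.cycle_bounds:
            raise ValueError(f"recording {r.recording_id} lacks cycle annotations")

    if mode == "participant_specific":
        train: dict[str, list[tuple[float, float]]] = {}
        val: dict[str, list[tuple[float, float]]] = {}
        test: list[str] = []
        by_key: dict[tuple[str, str], dict[int, SyntheticRecording]] = {}
        for r in recs:
            by_key.setdefault((r.subject_id, r.hand_position), {})[r.session_index] = r
        for key, sessions in sorted(by_key.items()):
            if len(sessions) < 2:
                raise ValueError(
                    f"subject/position {key} has a single recording; "
                    "participant-specific mode needs two"
                )
            first = sessions[min(sessions)]
            if len(first.cycle_bounds) < 3:
                raise ValueError(f"{first.recording_id} has fewer than 3 cycles")
            cb = first.cycle_bounds
            train[first.recording_id] = [(cb[0][0], cb[1][1])]
            val[first.recording_id] = [(cb[2][0], cb[2][1])]
            for s in sorted(sessions)[1:]:
                test.append(sessions[s].recording_id)
        return SplitPlan(mode=mode, train=train, val=val, test=test)

    if mode == "leave_one_out":
        subjects = sorted({r.subject_id for r in recs})
        if held_out is None or held_out not in subjects:
            raise ValueError(f"unknown held-out subject {held_out!r}")
        test = [r.recording_id for r in recs if r.subject_id == held_out]
        train = {}
        val = {}
        for r in recs:
            if r.subject_id == held_out:
                continue
            cb = r.cycle_bounds
            train[r.recording_id] = [(cb[0][0], cb[-2][1] if len(cb) > 1 else cb[0][1])]
            if len(cb) > 1:
                val[r.recording_id] = [(cb[-1][0], cb[-1][1])]
        cv_groups = [[s] for s in subjects if s != held_out]
        return SplitPlan(
            mode=mode, train=train, val=val, test=test,
            held_out_subject=held_out, cv_groups=cv_groups,
        )

    raise ValueError(f"unknown split mode {mode!r}")
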