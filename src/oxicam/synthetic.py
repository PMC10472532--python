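"""Synthetic optophysiological data generator.

Every downstream stage of the package is testable without any recorded
video because this module emulates the full measurement chain:

1. **Breath-hold protocol** — SpO2 trajectories for the protocol in which a
   participant breathes normally for 30-40 s, exhales fully, and holds the
   breath for another 30-40 s, repeated for three cycles.  Breath holds pull
   SpO2 from its ~98% baseline down by 5-10 percentage points (below 90% on
   deeper dips), with a circulatory response lag and exponential
   decay/recovery dynamics.
2. **Pulsatile skin color signals** — 30 fps R, G, B intensity series whose
   per-channel AC/DC modulation depends on SpO2 through the difference in
   light extinction between deoxygenated (Hb) and oxygenated (HbO2)
   hemoglobin: a large difference in the red band, a smaller one in blue,
   and essentially none in green.  Per channel c,

       x_c(t) = DC_c * (1 + PI * m_c(S(t)) * p(t)) + n(t),
       m_c(S) = eps_hb[c] * (1 - S/100) + eps_hbo2[c] * (S/100),

   where PI is the perfusion index (AC/DC scale), p(t) a unit-amplitude
   pulse waveform at the heart rate, and n(t) sensor noise.  The
   extinction-like constants are free simulator parameters chosen to honor
   the qualitative band ordering above; they are not literature values.
3. **Cohorts** — collections of recordings for several subjects in palm-up
   (PU) and palm-down (PD) positions with per-subject skin tone (DC levels)
   and heart rate.
4. **Rendered hand frames** — an elliptical skin-colored patch on a
   low-redness background, with ground-truth masks, for exercising the skin
   segmentation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .signals import SkinColorSignal, SpO2Trace

__all__ = [
    "BreathProtocolParams",
    "OptoModelParams",
    "SyntheticRecording",
    "generate_breath_protocol",
    "generate_spo2_trajectory",
    "generate_skin_signal",
    "generate_cohort",
    "render_synthetic_frames",
    "ror_curve",
]

log = logging.getLogger(__name__)

POSITIONS = ("PU", "PD")
FITZPATRICK_TAGS = ("II", "III", "IV", "V")


@dataclass
class BreathProtocolParams:
    """Parameters of the breath-hold protocol and the SpO2 response model.

    Durations are seconds, SpO2 quantities percent.  ``response_lag`` delays
    the onset of desaturation after the breath hold starts (finger-probe
    circulation delay); ``recovery_tau`` is the first-order time constant of
    both the desaturation and the resaturation transients.
    """

    n_cycles: int = 3
    normal_dur_range: tuple[float, float] = (30.0, 40.0)
    hold_dur_range: tuple[float, float] = (30.0, 40.0)
    baseline_spo2: float = 98.0
    dip_depth_range: tuple[float, float] = (5.0, 10.0)
    response_lag: float = 15.0
    recovery_tau: float = 10.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("normal_dur_range", "hold_dur_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive with lo <= hi")
        lo, hi = self.dip_depth_range
        if lo < 0 or hi < lo:
            raise ValueError("dip_depth_range must be non-negative with lo <= hi")
        if self.baseline_spo2 - hi < 70:
            raise ValueError("baseline - max dip must stay >= 70%")
        if self.response_lag < 0 or self.recovery_tau <= 0:
            raise ValueError("response_lag must be >= 0 and recovery_tau > 0")


@dataclass
class OptoModelParams:
    """Parameters of the pulsatile skin-signal model.

    ``dc_levels`` are baseline R, G, B intensities (0-255).  ``eps_hb`` /
    ``eps_hbo2`` are relative per-channel extinction-like constants for Hb
    and HbO2 (unitless simulator constants; red must absorb Hb more than
    HbO2, green must be insensitive).  ``perfusion_index`` scales AC/DC.
    """

    dc_levels: tuple[float, float, float] = (180.0, 120.0, 100.0)
    eps_hb: tuple[float, float, float] = (3.0, 1.0, 1.6)      # R, G, B
    eps_hbo2: tuple[float, float, float] = (0.5, 1.0, 1.1)    # R, G, B
    perfusion_index: float = 0.02
    heart_rate: float = 72.0
    noise_sd: float = 0.3
    fps: float = 30.0
    waveform: str = "raised_cosine"  # or "sine"
    drift_amplitude: float = 0.0     # slow multiplicative DC drift (PD realism)
    drift_freq: float = 0.05         # Hz

    def validate(self) -> None:
        if any(d <= 0 for d in self.dc_levels):
            raise ValueError("dc_levels must be positive")
        if self.eps_hb[0] <= self.eps_hbo2[0]:
            raise ValueError("red channel requires eps_hb > eps_hbo2")
        if abs(self.eps_hb[1] - self.eps_hbo2[1]) > 0.05:
            raise ValueError("green channel must be (nearly) insensitive to SpO2")
        if not (60.0 <= self.heart_rate <= 120.0):
            raise ValueError("heart_rate must lie in [60, 120] bpm")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.perfusion_index <= 0:
            raise ValueError("perfusion_index must be positive")
        if self.waveform not in ("raised_cosine", "sine"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    def modulation(self, spo2) -> np.ndarray:
        """m_c(S) for each channel; shape (3,) + shape of ``spo2``."""
        s = np.asarray(spo2, dtype=float) / 100.0
        eps_hb = np.asarray(self.eps_hb)
        eps_hbo2 = np.asarray(self.eps_hbo2)
        return eps_hb[:, None] * (1.0 - s)[None, :] + eps_hbo2[:, None] * s[None, :]


@dataclass
class ProtocolInfo:
    """Realized protocol timing: per-cycle phase durations and boundaries."""

    normal_durations: np.ndarray
    hold_durations: np.ndarray
    dip_depths: np.ndarray
    cycle_bounds: list[tuple[float, float]]
    tail: float

    @property
    def total_duration(self) -> float:
        return float(self.cycle_bounds[-1][1])


@dataclass
class SyntheticRecording:
    """One synthetic session: skin color signal + 1 Hz reference + metadata."""

    signal: SkinColorSignal
    reference: SpO2Trace
    subject_id: str
    hand_position: str
    skin_tone_tag: str
    session_index: int
    cycle_bounds: list[tuple[float, float]] = field(default_factory=list)
    opto: OptoModelParams | None = None

    def __post_init__(self) -> None:
        if self.hand_position not in POSITIONS:
            raise ValueError(f"hand_position must be one of {POSITIONS}")
        if self.signal.duration + 1e-6 < self.reference.duration:
            raise ValueError("signal must cover the reference duration")

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}_{self.hand_position}_s{self.session_index}"


def generate_breath_protocol(
    params: BreathProtocolParams | None = None,
) -> tuple[SpO2Trace, ProtocolInfo]:
    """Simulate a breath-hold protocol SpO2 trajectory at 1 Hz.

    Each cycle is a normal-breathing phase at baseline followed by a breath
    hold.  The SpO2 target drops to ``baseline - dip`` from ``response_lag``
    seconds after the hold starts until ``response_lag`` seconds after it
    ends, and the measured SpO2 relaxes toward the target with first-order
    dynamics (time constant ``recovery_tau``).  A recovery tail of
    ``response_lag + 4 * recovery_tau`` seconds is appended after the last
    hold so the trace returns to baseline.  Values are clipped to [70, 100].
    """
    params = params or BreathProtocolParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    normals = rng.uniform(*params.normal_dur_range, size=params.n_cycles)
    holds = rng.uniform(*params.hold_dur_range, size=params.n_cycles)
    dips = rng.uniform(*params.dip_depth_range, size=params.n_cycles)

    tail = params.response_lag + 4.0 * params.recovery_tau
    cycle_bounds: list[tuple[float, float]] = []
    dip_windows: list[tuple[float, float, float]] = []
    t0 = 0.0
    for i in range(params.n_cycles):
        hold_start = t0 + normals[i]
        hold_end = hold_start + holds[i]
        dip_windows.append((hold_start + params.response_lag, hold_end + params.response_lag, dips[i]))
        end = hold_end + (tail if i == params.n_cycles - 1 else 0.0)
        cycle_bounds.append((t0, end))
        t0 = end

    total = cycle_bounds[-1][1]
    times = np.arange(0.0, np.floor(total) + 1.0)
    target = np.full_like(times, params.baseline_spo2)
    for lo, hi, dip in dip_windows:
        target[(times >= lo) & (times < hi)] = params.baseline_spo2 - dip

    # first-order relaxation toward the target at 1 Hz steps
    alpha = 1.0 - np.exp(-1.0 / params.recovery_tau)
    values = np.empty_like(times)
    s = params.baseline_spo2
    for k in range(times.size):
        s = s + (target[k] - s) * alpha
        values[k] = s
    values = np.clip(values, 70.0, 100.0)

    info = ProtocolInfo(
        normal_durations=normals,
        hold_durations=holds,
        dip_depths=dips,
        cycle_bounds=cycle_bounds,
        tail=tail,
    )
    trace = SpO2Trace(times=times, values=values, rate=1.0, meta={"protocol": params})
    return trace, info


def generate_spo2_trajectory(params: BreathProtocolParams | None = None) -> SpO2Trace:
    """Breath-protocol SpO2 trajectory (see :func:`generate_breath_protocol`)."""
    trace, _ = generate_breath_protocol(params)
    return trace


def _pulse_waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Zero-mean, unit-amplitude pulse waveform as a function of beat phase.

    ``sine`` gives sin(2*pi*phase) (RMS 1/sqrt(2)), handy for closed-form
    checks.  ``raised_cosine`` gives a PPG-like systolic bump: a raised
    cosine occupying the first 40% of the beat, mean-removed and peak-scaled
    to unit amplitude.
    """
    frac = np.mod(phase, 1.0)
    if kind == "sine":
        return np.sin(2.0 * np.pi * frac)
    # Raised cosine over the first `width` of the beat; its beat-long mean is
    # 0.5 * width, removed so the DC level stays the generator's DC.
    width = 0.4
    bump = np.where(frac < width, 0.5 * (1.0 - np.cos(2.0 * np.pi * frac / width)), 0.0)
    bump = bump - 0.5 * width
    return bump / (1.0 - 0.5 * width)


def generate_skin_signal(
    trajectory: SpO2Trace,
    opto: OptoModelParams | None = None,
    seed: int | None = None,
) -> SkinColorSignal:
    """Synthesize a pulsatile RGB skin color signal from an SpO2 trajectory.

    Implements x_c(t) = DC_c (1 + PI m_c(S(t)) p(t)) + n(t) at ``opto.fps``,
    with optional slow multiplicative drift, and clips to [0, 255] (clipping
    events are logged).
    """
    opto = opto or OptoModelParams()
    opto.validate()
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, trajectory.duration + 1.0 / opto.fps / 2, 1.0 / opto.fps)
    t = t + trajectory.times[0]
    s_t = np.interp(t, trajectory.times, trajectory.values)

    p = _pulse_waveform(t * opto.heart_rate / 60.0, opto.waveform)
    m = opto.modulation(s_t)  # (3, T)
    dc = np.asarray(opto.dc_levels, dtype=float)[:, None]
    x = dc * (1.0 + opto.perfusion_index * m * p[None, :])
    if opto.drift_amplitude > 0:
        drift = opto.drift_amplitude * np.sin(2.0 * np.pi * opto.drift_freq * t)
        x = x * (1.0 + drift[None, :])
    if opto.noise_sd > 0:
        x = x + rng.normal(0.0, opto.noise_sd, size=x.shape)

    n_clip = int(np.sum((x < 0) | (x > 255)))
    if n_clip:
        log.warning("generate_skin_signal: clipped %d samples to [0, 255]", n_clip)
    x = np.clip(x, 0.0, 255.0)
    return SkinColorSignal(values=x, fps=opto.fps)


def ror_curve(opto: OptoModelParams, spo2: np.ndarray) -> np.ndarray:
    """Ground-truth ratio-of-ratios RR(S) = m_red(S) / m_blue(S).

    The pulse waveform is common to all channels, so AC/DC ratios reduce to
    PI * m_c(S) and the waveform cancels in the ratio.
    """
    m = opto.modulation(np.asarray(spo2, dtype=float))
    return m[0] / m[2]


def _subject_opto(rng: np.random.Generator, position: str) -> tuple[OptoModelParams, str]:
    """Draw per-subject optical parameters (skin tone, heart rate)."""
    tone_idx = rng.integers(0, len(FITZPATRICK_TAGS))
    tone = FITZPATRICK_TAGS[tone_idx]
    # darker skin tones -> lower baseline reflectance
    tone_scale = {"II": 1.0, "III": 0.9, "IV": 0.75, "V": 0.6}[tone]
    base = np.array([180.0, 120.0, 100.0]) * tone_scale
    base = base * rng.uniform(0.9, 1.1, size=3)
    hr = float(rng.uniform(60.0, 120.0))
    opto = OptoModelParams(heart_rate=hr)
    if position == "PD":
        # back of the hand: darker, with extra slow illumination drift
        base = base * 0.8
        opto = replace(opto, drift_amplitude=0.01)
    opto = replace(opto, dc_levels=tuple(base))
    return opto, tone


def generate_cohort(
    n_subjects: int = 14,
    sessions_per_position: int = 2,
    positions: tuple[str, ...] = ("PU", "PD"),
    seed: int | None = None,
    protocol: BreathProtocolParams | None = None,
    opto_overrides: dict | None = None,
) -> list[SyntheticRecording]:
    """Generate a full synthetic study cohort.

    Returns ``n_subjects * sessions_per_position * len(positions)``
    recordings (14 x 2 x 2 = 56 at the defaults, matching a two-session
    PU/PD study design).  Per-subject DC levels (skin tone) and heart rate
    are randomized; the whole cohort is a pure function of ``seed``.
    ``opto_overrides`` fields (e.g. ``noise_sd=0``) replace the drawn
    optical parameters for every recording.
    """
    if n_subjects < 1 or sessions_per_position < 1 or len(positions) < 1:
        raise ValueError("counts must be >= 1")
    for p in positions:
        if p not in POSITIONS:
            raise ValueError(f"unknown position {p!r}")
    base_protocol = protocol or BreathProtocolParams()
    ss = np.random.SeedSequence(seed)
    recordings: list[SyntheticRecording] = []
    for subj in range(n_subjects):
        subj_ss = ss.spawn(1)[0]
        rng = np.random.default_rng(subj_ss)
        subject_id = f"S{subj + 1:02d}"
        tone_draw_rng = np.random.default_rng(subj_ss.spawn(1)[0])
        for position in positions:
            opto, tone = _subject_opto(tone_draw_rng, position)
            if opto_overrides:
                opto = replace(opto, **opto_overrides)
            for session in range(1, sessions_per_position + 1):
                proto = replace(base_protocol, seed=int(rng.integers(0, 2**31 - 1)))
                trace, info = generate_breath_protocol(proto)
                sig = generate_skin_signal(
                    trace, opto, seed=int(rng.integers(0, 2**31 - 1))
                )
                recordings.append(
                    SyntheticRecording(
                        signal=sig,
                        reference=trace,
                        subject_id=subject_id,
                        hand_position=position,
                        skin_tone_tag=tone,
                        session_index=session,
                        cycle_bounds=info.cycle_bounds,
                        opto=opto,
                    )
                )
    return recordings


def render_synthetic_frames(
    signal: SkinColorSignal,
    frame_shape: tuple[int, int] = (48, 64),
    ellipse_axes: tuple[float, float] = (16.0, 22.0),
    background_rgb: tuple[float, float, float] = (90.0, 130.0, 110.0),
    pixel_noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a frame sequence with a skin-colored ellipse on a low-Cr background.

    Per frame, the ellipse pixels take that frame's (R, G, B) signal value
    plus i.i.d. pixel noise; the greenish background has low Cr so a
    red-chroma threshold separates the two.  Returns ``(frames, mask)``
    where ``frames`` has shape (T, H, W, 3) and ``mask`` the ground-truth
    boolean ellipse.
    """
    h, w = frame_shape
    ay, ax = ellipse_axes
    if ay <= 0 or ax <= 0:
        raise ValueError("ellipse axes must be positive")
    if 2 * ay >= h or 2 * ax >= w:
        raise ValueError("ellipse larger than frame")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - (h - 1) / 2.0) / ay) ** 2 + ((xx - (w - 1) / 2.0) / ax) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("ellipse area is zero")

    rng = np.random.default_rng(seed)
    T = signal.n_frames
    frames = np.empty((T, h, w, 3), dtype=float)
    frames[:] = np.asarray(background_rgb, dtype=float)
    for t in range(T):
        frames[t][mask] = signal.values[:, t]
    if pixel_noise_sd > 0:
        frames += rng.normal(0.0, pixel_noise_sd, size=frames.shape)
    np.clip(frames, 0.0, 255.0, out=frames)
    return frames, mask
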