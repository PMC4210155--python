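"""EMG conditioning, heel-strike detection, stride segmentation and ERAs.

Raw surface EMG is reduced to its linear envelope — band-pass filtered
(20–500 Hz, linear-phase FIR) to remove motion artefacts and offsets,
full-wave rectified, then low-pass filtered with a zero-lag fourth-order
Butterworth at 6 Hz.  Heel strikes are detected from the heel FSR channel
as threshold crossings refined back to the loading onset; strides span
ipsilateral heel strike to the next ipsilateral heel strike.  Event-related
averages (ERAs) align the envelope to heel contact over ±1 stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "EnvelopeSignal",
    "GaitEvents",
    "StrideSegmentation",
    "ERACurve",
    "condition_emg",
    "detect_heel_strikes",
    "segment_strides",
    "event_related_average",
    "mean_heel_template",
]


@dataclass
class EnvelopeSignal:
    """Non-negative linear envelope of one EMG channel."""

    values: np.ndarray
    rate_hz: float
    muscle: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GaitEvents:
    """Heel-strike times per foot, in seconds."""

    left_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    right_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: belt speed (m/s) at each left heel strike, when known (synthetic data)
    left_speeds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.left_times = np.asarray(self.left_times, dtype=float)
        self.right_times = np.asarray(self.right_times, dtype=float)
        for t in (self.left_times, self.right_times):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("heel-strike times must be strictly increasing")

    def times(self, foot: str) -> np.ndarray:
        return {"left": self.left_times, "right": self.right_times}[foot]


@dataclass(frozen=True)
class StrideSegmentation:
    """Completed stride segmentation for one reference foot."""

    foot: str
    start_times: np.ndarray  # stride onsets (reference-foot strikes), s
    durations: np.ndarray  # per-stride durations, s
    mean_duration_s: float

    @property
    def n_strides(self) -> int:
        return len(self.durations)


@dataclass(frozen=True)
class ERACurve:
    """Event-related average over a symmetric ±1-stride lag window."""

    lags_s: np.ndarray
    mean: np.ndarray
    n_events: int
    n_dropped: int


def condition_emg(raw: np.ndarray, rate_hz: float, muscle: str = "",
                  band_hz: tuple[float, float] = (20.0, 500.0),
                  lowpass_hz: float = 6.0) -> EnvelopeSignal:
    """Linear envelope: band-pass FIR -> full-wave rectify -> zero-lag LP.

    The band-pass is a linear-phase windowed-sinc (Blackman) FIR of order
    ~4x(rate/low edge), applied with its group delay compensated; the
    low-pass is a fourth-order Butterworth run forward-backward (zero lag).
    Residual negative values after filtering are clipped to zero.
    """
    x = np.asarray(raw, dtype=float)
    nyq = rate_hz / 2.0
    lo, hi = band_hz
    if nyq < hi:
        raise ValueError(
            f"sampling rate {rate_hz} Hz cannot represent the {hi} Hz band edge"
        )
    hi = min(hi, 0.995 * nyq)  # keep the upper edge strictly below Nyquist
    numtaps = int(4 * rate_hz / lo) | 1  # odd -> integer group delay
    if x.size <= numtaps:
        raise ValueError("signal shorter than the band-pass filter warm-up")
    # Blackman window: ~-74 dB stopband so DC/offset leakage stays below 1e-3
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, window="blackman", fs=rate_hz)
    bp = signal.fftconvolve(x, taps, mode="same")  # zero net delay (symmetric taps)
    rect = np.abs(bp)
    sos = signal.butter(4, lowpass_hz, btype="low", fs=rate_hz, output="sos")
    env = signal.sosfiltfilt(sos, rect)
    return EnvelopeSignal(values=np.clip(env, 0.0, None), rate_hz=rate_hz, muscle=muscle)


def detect_heel_strikes(
    heel: np.ndarray,
    rate_hz: float,
    threshold_frac: float = 0.1,
    debounce_s: float = 0.2,
    refine_onset: bool = True,
) -> np.ndarray:
    """Heel-strike times from one heel FSR channel.

    Rising crossings of ``threshold_frac x channel max`` are found, merged
    within a debounce window, and (by default) refined backwards along the
    monotone loading flank to the onset sample, so that on clean signals
    the returned times match the true loading onsets to ±1 sample.
    Detection is invariant to positive rescaling of the channel.  An
    all-zero (or constant) channel yields no events.
    """
    x = np.asarray(heel, dtype=float)
    peak = float(np.max(x)) if x.size else 0.0
    if peak <= 0 or np.ptp(x) == 0:
        return np.empty(0)
    thr = threshold_frac * peak
    above = x >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    debounce_n = int(round(debounce_s * rate_hz))
    kept = [int(crossings[0])]
    for c in crossings[1:]:
        if c - kept[-1] >= debounce_n:
            kept.append(int(c))
    if refine_onset:
        eps = 1e-9 * peak
        onsets = []
        for c in kept:
            j = c
            while j > 0 and x[j - 1] < x[j] and x[j - 1] > eps:
                j -= 1
            onsets.append(j)
        kept = onsets
    return np.asarray(kept, dtype=float) / rate_hz


def segment_strides(events: GaitEvents, foot: str = "left") -> StrideSegmentation:
    """Strides from ipsilateral strike to the next ipsilateral strike."""
    t = events.times(foot)
    if t.size < 2:
        raise ValueError("need at least two heel strikes to segment strides")
    durations = np.diff(t)
    if np.any(durations <= 0):
        raise ValueError("non-positive stride duration")
    return StrideSegmentation(
        foot=foot,
        start_times=t[:-1],
        durations=durations,
        mean_duration_s=float(durations.mean()),
    )


def event_related_average(
    values: np.ndarray,
    rate_hz: float,
    event_times: np.ndarray,
    stride_s: float,
) -> ERACurve:
    """Average a signal in ±1-stride windows around each event.

    Events whose full window does not fit inside the recording are dropped
    and counted in ``n_dropped``.
    """
    x = np.asarray(values, dtype=float)
    half = int(round(stride_s * rate_hz))
    idx = np.round(np.asarray(event_times, dtype=float) * rate_hz).astype(int)
    usable = idx[(idx - half >= 0) & (idx + half < x.size)]
    if usable.size == 0:
        raise ValueError("no event has a full ±1-stride window inside the recording")
    windows = np.stack([x[i - half : i + half + 1] for i in usable])
    lags = np.arange(-half, half + 1) / rate_hz
    return ERACurve(
        lags_s=lags,
        mean=windows.mean(axis=0),
        n_events=int(usable.size),
        n_dropped=int(idx.size - usable.size),
    )


def mean_heel_template(
    heel: np.ndarray, rate_hz: float, seg: StrideSegmentation
) -> np.ndarray:
    """Mean heel-contact loading curve over strides, one mean stride long.

    Each stride's heel segment is linearly resampled to the mean stride
    length before averaging, so the template length equals one mean stride
    duration regardless of stride-to-stride timing variability.
    """
    x = np.asarray(heel, dtype=float)
    if seg.n_strides < 1:
        raise ValueError("need at least one complete stride")
    n_out = int(round(seg.mean_duration_s * rate_hz))
    grid = np.arange(n_out) / n_out
    stack = []
    for t0, dur in zip(seg.start_times, seg.durations):
        i0 = int(round(t0 * rate_hz))
        n = int(round(dur * rate_hz))
        if i0 + n > x.size:
            continue
        segvals = x[i0 : i0 + n]
        stack.append(np.interp(grid, np.arange(n) / n, segvals))
    if not stack:
        raise ValueError("no stride segment fits inside the recording")
    return np.mean(stack, axis=0)
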