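"""From identified impulse responses to joint-action transfer segments.

The truncated heel-contact -> envelope responses are convolved with the
mean FSR heel-contact template so an *impulse* trigger (the walker's foot
switch) elicits the same activation as a typical FSR loading curve.  The
peaks and troughs of the resulting one-stride curves are located, and the
data between the trough minimum preceding each peak and the subsequent
trough minimum is extracted as a joint-action segment, following the
muscle-to-joint mapping:

* rectus femoris / contralateral heel: first (swing-phase) peak -> hip
  flexion; second (terminal-swing) peak -> knee extension, re-triggered by
  the hip anterior extreme angle with the segment starting at the
  preceding trough minimum;
* biceps femoris / ipsilateral heel: stance peak -> hip extension;
* biceps femoris + lateral gastrocnemius / contralateral heel: the two
  knee-flexor contributions are summed;
* tibialis anterior acts only on the (rigid) ankle and is excluded.

Knee segments have their trigger-to-onset delay removed (the walker's knee
springs supply an equivalent mechanical latency); hip segments keep it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sp_signal

__all__ = [
    "TransferCurve",
    "ActionSegment",
    "fsr_convolve",
    "locate_landmarks",
    "extract_action_segment",
    "combine_knee_flexors",
    "align_knee_onset",
    "build_action_segments",
]


@dataclass(frozen=True)
class Landmark:
    index: int
    kind: str  # "peak" | "trough"
    value: float

    @property
    def is_peak(self) -> bool:
        return self.kind == "peak"


@dataclass
class TransferCurve:
    """One-stride FSR-convolved response with located landmarks."""

    H: np.ndarray
    rate_hz: float
    trigger: str  # CH | IH | AEA
    landmarks: list[Landmark] = field(default_factory=list)

    @property
    def peaks(self) -> list[Landmark]:
        return [m for m in self.landmarks if m.is_peak]


@dataclass
class ActionSegment:
    """Trough-to-trough activation segment for one joint action."""

    joint: str  # hip | knee
    action: str  # flexion | extension
    values: np.ndarray
    rate_hz: float
    trigger: str
    onset_delay_s: float
    boundary_flags: tuple[bool, bool] = (False, False)  # missing lead/trail trough

    @property
    def t_s(self) -> np.ndarray:
        return self.onset_delay_s + np.arange(len(self.values)) / self.rate_hz


def fsr_convolve(h: np.ndarray, u: np.ndarray, rate_hz: float, trigger: str = "CH") -> TransferCurve:
    """H = h ⊛ u, truncated to one stride (the length of ``u``).

    ``u`` is the mean heel-contact template; after this convolution an
    impulse input reproduces the response to a typical FSR loading curve.
    """
    h = np.asarray(h, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("empty heel template")
    H = sp_signal.fftconvolve(h, u)[: u.size]
    return TransferCurve(H=H, rate_hz=rate_hz, trigger=trigger)


def locate_landmarks(curve: TransferCurve, smooth_ms: float = 25.0) -> TransferCurve:
    """Alternating trough/peak landmarks of the smoothed curve.

    A short moving average (default 25 ms) suppresses coefficient noise
    before extremum detection; ties/plateaus resolve to the earliest time.
    Boundary samples act as implicit troughs when a peak has no interior
    flanking trough (flagged downstream by segment extraction).
    """
    H = curve.H
    if H.size < 3 or np.ptp(H) == 0:
        raise ValueError("curve has no interior extremum")
    w = max(int(round(smooth_ms * curve.rate_hz / 1000.0)), 1)
    s = ndimage.uniform_filter1d(H, w, mode="nearest")
    prom = 0.02 * float(np.ptp(s))  # ignore ripples below 2% of the range
    pk, _ = sp_signal.find_peaks(s, prominence=prom)
    tr, _ = sp_signal.find_peaks(-s, prominence=prom)
    if pk.size == 0:
        raise ValueError("curve has no interior peak")
    marks = sorted(
        [Landmark(int(i), "peak", float(s[i])) for i in pk]
        + [Landmark(int(i), "trough", float(s[i])) for i in tr],
        key=lambda m: m.index,
    )
    # collapse same-kind runs, keeping the more extreme member
    out: list[Landmark] = []
    for m in marks:
        if out and out[-1].kind == m.kind:
            if (m.is_peak and m.value > out[-1].value) or (
                not m.is_peak and m.value < out[-1].value
            ):
                out[-1] = m
        else:
            out.append(m)
    # every peak must be flanked by troughs: curve ends act as troughs when
    # no interior one exists (segment extraction flags these)
    if out and out[0].is_peak:
        i = int(np.argmin(s[: out[0].index])) if out[0].index > 0 else 0
        out.insert(0, Landmark(i, "trough", float(s[i])))
    if out and out[-1].is_peak:
        j = out[-1].index
        i = j + 1 + int(np.argmin(s[j + 1 :])) if j < s.size - 1 else s.size - 1
        out.append(Landmark(i, "trough", float(s[i])))
    curve.landmarks = out
    return curve


def extract_action_segment(
    curve: TransferCurve, which_peak: int, joint: str, action: str,
    trigger: str | None = None,
) -> ActionSegment:
    """Segment from the trough minimum before peak ``which_peak`` (0-based,
    in time order) to the subsequent trough minimum."""
    if not curve.landmarks:
        locate_landmarks(curve)
    peaks = curve.peaks
    if which_peak >= len(peaks):
        raise ValueError(f"curve has {len(peaks)} peaks, requested #{which_peak}")
    peak = peaks[which_peak]
    troughs = [m for m in curve.landmarks if not m.is_peak]
    before = [m for m in troughs if m.index < peak.index]
    after = [m for m in troughs if m.index > peak.index]
    i0 = before[-1].index if before else 0
    i1 = after[0].index if after else curve.H.size - 1
    return ActionSegment(
        joint=joint,
        action=action,
        values=curve.H[i0 : i1 + 1].copy(),
        rate_hz=curve.rate_hz,
        trigger=trigger if trigger is not None else curve.trigger,
        onset_delay_s=i0 / curve.rate_hz,
        boundary_flags=(not before, not after),
    )


def combine_knee_flexors(a: ActionSegment, b: ActionSegment) -> ActionSegment:
    """Sum two knee-flexion segments on the union of their supports."""
    for s in (a, b):
        if (s.joint, s.action) != ("knee", "flexion"):
            raise ValueError("both segments must be knee flexion")
    if a.trigger != b.trigger:
        raise ValueError("knee-flexor segments must share the trigger")
    if a.rate_hz != b.rate_hz:
        raise ValueError("segments must share the sampling rate")
    rate = a.rate_hz
    i0 = min(int(round(s.onset_delay_s * rate)) for s in (a, b))
    i1 = max(int(round(s.onset_delay_s * rate)) + len(s.values) for s in (a, b))
    out = np.zeros(i1 - i0)
    for s in (a, b):
        j = int(round(s.onset_delay_s * rate)) - i0
        out[j : j + len(s.values)] += s.values
    return ActionSegment(
        joint="knee", action="flexion", values=out, rate_hz=rate,
        trigger=a.trigger, onset_delay_s=i0 / rate,
        boundary_flags=(a.boundary_flags[0] or b.boundary_flags[0],
                        a.boundary_flags[1] or b.boundary_flags[1]),
    )


def align_knee_onset(seg: ActionSegment) -> ActionSegment:
    """Remove the trigger-to-onset delay (segment starts at the trigger).

    Applied to knee segments only: the walker's knee springs already delay
    motion mechanically, so keeping the physiological delay would double
    it.  Hip segments keep their delay and should not pass through here.
    """
    if np.ptp(seg.values) == 0:
        raise ValueError("flat segment: onset undetectable")
    return ActionSegment(
        joint=seg.joint, action=seg.action, values=seg.values.copy(),
        rate_hz=seg.rate_hz, trigger=seg.trigger, onset_delay_s=0.0,
        boundary_flags=seg.boundary_flags,
    )


def build_action_segments(
    curves: dict[tuple[str, str], TransferCurve],
) -> dict[str, ActionSegment]:
    """The four joint-action segments from the per-muscle transfer curves.

    ``curves`` maps (muscle, trigger-foot) — ("RF","CH"), ("BF","IH"),
    ("BF","CH"), ("LG","CH") — to their one-stride transfer curves.
    Returns hip_flexion, hip_extension, knee_flexion, knee_extension
    segments wired to their triggers (CH / IH / CH / AEA).
    """
    for key in (("RF", "CH"), ("BF", "IH"), ("BF", "CH"), ("LG", "CH")):
        if key not in curves:
            raise ValueError(f"missing transfer curve for {key}")

    rf = locate_landmarks(curves[("RF", "CH")])
    peaks = rf.peaks
    if len(peaks) < 2:
        raise ValueError(
            "rectus femoris curve must show two peaks (swing hip flexion and "
            f"terminal-swing knee extension); found {len(peaks)}"
        )
    # the swing-phase peak precedes mid-stride; the knee-extension burst
    # sits at terminal swing — disambiguate by position relative to 50%,
    # taking the dominant peak on each side
    half = rf.H.size // 2
    early = [i for i, p in enumerate(peaks) if p.index < half]
    hip_peak = max(early, key=lambda i: peaks[i].value) if early else 0
    late_candidates = [i for i in range(len(peaks)) if i != hip_peak]
    knee_peak = max(late_candidates, key=lambda i: peaks[i].value)

    hip_flex = extract_action_segment(rf, hip_peak, "hip", "flexion")
    knee_ext = align_knee_onset(
        extract_action_segment(rf, knee_peak, "knee", "extension", trigger="AEA")
    )

    bf_ih = locate_landmarks(curves[("BF", "IH")])
    stance_peak = max(range(len(bf_ih.peaks)), key=lambda i: bf_ih.peaks[i].value)
    hip_ext = extract_action_segment(bf_ih, stance_peak, "hip", "extension")

    def knee_flex_from(curve: TransferCurve) -> ActionSegment:
        locate_landmarks(curve)
        best = max(range(len(curve.peaks)), key=lambda i: curve.peaks[i].value)
        return extract_action_segment(curve, best, "knee", "flexion")

    knee_flex = align_knee_onset(
        combine_knee_flexors(
            knee_flex_from(curves[("BF", "CH")]),
            knee_flex_from(curves[("LG", "CH")]),
        )
    )
    return {
        "hip_flexion": hip_flex,
        "hip_extension": hip_ext,
        "knee_flexion": knee_flex,
        "knee_extension": knee_ext,
    }
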