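"""Synthetic treadmill-walking recordings with known ground truth.

Emulates the study conditions end-to-end so every downstream stage is
testable without real recordings: a pseudo-random belt-speed profile with
0.05–0.1 m/s increments, alternating heel strikes with a speed-dependent
cadence, smooth FSR loading curves during stance, and EMG whose linear
envelope is the convolution of the heel-contact signals with known
per-muscle kernels, amplitude-modulated by a speed-related gain and carried
on band-limited (20–500 Hz) noise.

All randomness descends from the single ``SynthConfig.seed``; each stage
draws from its own child stream (fixed spawn keys), so outputs are
reproducible and independent of call order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import DEFAULT_CHANNELS, Recording, write_recording
from .preprocessing import GaitEvents
from .twitch import CurveParams, model_curve

__all__ = [
    "SpeedProfile",
    "GroundTruthKernel",
    "SynthConfig",
    "stride_duration",
    "generate_speed_sequence",
    "generate_gait_events",
    "generate_fsr_signals",
    "generate_emg",
    "generate_recording",
    "default_kernels",
    "write_fixture",
]

_INCR_MIN, _INCR_MAX = 0.05, 0.10  # legal belt-speed increments, m/s
_QUANTUM = 0.05

# child-stream spawn keys (documented stream order)
_STREAM_SPEED, _STREAM_EVENTS, _STREAM_EMG = 1, 2, 3


@dataclass(frozen=True)
class SpeedProfile:
    """Sequence of (belt speed m/s, hold duration s) treadmill settings."""

    settings: tuple[tuple[float, float], ...]
    strides_per_setting: int

    @property
    def speeds(self) -> np.ndarray:
        return np.array([s for s, _ in self.settings])

    @property
    def total_range(self) -> float:
        v = self.speeds
        return float(v.max() - v.min())

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.settings))


@dataclass(frozen=True)
class GroundTruthKernel:
    """True heel-contact -> envelope impulse response for one pairing.

    ``foot`` is the triggering heel relative to the muscle's leg:
    CH = contralateral, IH = ipsilateral.  Coefficients are sampled at the
    recording rate and last at most one nominal stride.
    """

    muscle: str  # TA | LG | RF | BF
    foot: str  # CH | IH
    coefficients: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if not np.isfinite(self.coefficients).all():
            raise ValueError("kernel coefficients must be finite")
        if self.foot not in ("CH", "IH"):
            raise ValueError("foot must be CH or IH")

    @property
    def duration_s(self) -> float:
        return len(self.coefficients) / self.rate_hz


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings emulating the recording conditions."""

    rate_hz: float = 1000.0
    carrier_band_hz: tuple[float, float] = (20.0, 500.0)
    envelope_snr: float = 20.0  # envelope peak / additive noise-floor envelope
    speed_gain: float = 0.5  # fractional envelope gain per m/s above min speed
    stride_length_m: float = 1.4  # cadence model: T(v) = stride_length / v
    stride_clip_s: tuple[float, float] = (0.8, 1.6)
    stride_jitter: float = 0.02  # fractional SD of stride-to-stride duration
    #: heel-loading window as a fraction of the stride: the heel FSR loads at
    #: heel strike and unloads again around heel-off, well before stance ends
    stance_frac: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 2 * self.carrier_band_hz[1]:
            raise ValueError("sampling rate must exceed twice the carrier band edge")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def stride_duration(speed: float | np.ndarray, config: SynthConfig) -> np.ndarray:
    """Cadence model: stride duration ~ stride length / speed, clipped."""
    lo, hi = config.stride_clip_s
    return np.clip(config.stride_length_m / np.asarray(speed, dtype=float), lo, hi)


def generate_speed_sequence(
    n_settings: int,
    speed_range: tuple[float, float],
    repeats: int = 1,
    seed: int = 0,
    strides_per_setting: int = 25,
    config: SynthConfig | None = None,
) -> SpeedProfile:
    """Pseudo-random belt-speed walk with legal increments.

    Speeds live on a 0.05 m/s grid inside ``speed_range``; each change is
    0.05 or 0.1 m/s.  The walk starts at the range minimum, sweeps with a
    persistent direction (reflecting at the bounds so both ends of the
    range are visited), and is steered back near its start at the end so
    that repeating the sequence never needs an illegal jump.  Hold
    durations give ``strides_per_setting`` strides at the setting's cadence.
    """
    if n_settings < 1:
        raise ValueError("n_settings must be >= 1")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    vmin, vmax = speed_range
    if not (0.5 <= vmin <= vmax <= 2.5):
        raise ValueError("speed range must lie within [0.5, 2.5] m/s")
    width_q = int(round((vmax - vmin) / _QUANTUM))
    if n_settings > 1 and width_q < 1:
        raise ValueError("speed range narrower than one 0.05 m/s increment")
    config = config or SynthConfig(seed=seed)
    rng = np.random.default_rng((seed, _STREAM_SPEED))

    if n_settings == 1:
        quanta = [0]
    else:
        d, direction = 0, +1
        quanta = [d]
        for k in range(1, n_settings):
            remaining = n_settings - 1 - k
            step = int(rng.integers(1, 3))  # 1 or 2 quanta = 0.05 or 0.1 m/s
            step = min(step, width_q) or 1
            if d + direction * step > width_q or d + direction * step < 0:
                direction = -direction
            nd = d + direction * step
            nd = min(max(nd, 0), width_q)
            if nd == d:  # bound pinch (very narrow range): force the other way
                nd = d - direction * step
            # steer home: keep the end reachable within 2 quanta of the start
            if nd > 2 * remaining + 2:
                nd = d - min(2, d)
                direction = -1
            d = nd
            quanta.append(d)

    speeds = vmin + _QUANTUM * np.asarray(quanta, dtype=float)
    speeds = np.tile(speeds, repeats)
    holds = strides_per_setting * stride_duration(speeds, config)
    settings = tuple((float(v), float(h)) for v, h in zip(speeds, holds))
    return SpeedProfile(settings=settings, strides_per_setting=strides_per_setting)


def generate_gait_events(profile: SpeedProfile, config: SynthConfig) -> GaitEvents:
    """Alternating left/right heel strikes following the speed profile.

    Each setting contributes ``strides_per_setting`` strides at the
    cadence-model duration with small multiplicative jitter; the
    contralateral (right) strike falls near mid-stride.
    """
    rng = config.rng(_STREAM_EVENTS)
    left, right, speeds = [], [], []
    t = 0.0
    for v, _hold in profile.settings:
        base = float(stride_duration(v, config))
        if base <= 0:
            raise ValueError("non-positive stride duration")
        for _ in range(profile.strides_per_setting):
            dur = base * (1.0 + config.stride_jitter * rng.standard_normal())
            dur = max(dur, 0.25 * base)
            left.append(t)
            speeds.append(v)
            phase = 0.5 * (1.0 + 0.02 * rng.standard_normal())
            right.append(t + np.clip(phase, 0.3, 0.7) * dur)
            t += dur
    left.append(t)  # closing strike so the last stride is complete
    speeds.append(profile.settings[-1][0])
    return GaitEvents(
        left_times=np.array(left),
        right_times=np.array(right),
        left_speeds=np.array(speeds),
    )


#: fraction of stance taken by the loading attack; heel-strike impact loads
#: the FSR much faster than the body-weight roll-off unloads it
_RISE_FRAC = 0.15


def _heel_channel(
    times: np.ndarray, n: int, rate: float, stance_n: np.ndarray
) -> np.ndarray:
    """Asymmetric loading pulse per stance: fast half-cosine attack at heel
    strike, slow raised-cosine unloading; zero in swing."""
    x = np.zeros(n)
    idx = np.round(times * rate).astype(int)
    for j in range(len(idx)):
        i0, w = idx[j], int(stance_n[j])
        if j + 1 < len(idx) and i0 + w > idx[j + 1]:
            raise ValueError("overlapping stances on one foot")
        rise = max(int(_RISE_FRAC * w), 2)
        s = np.arange(min(w, max(n - i0, 0)))
        if s.size and i0 >= 0:
            x[i0 : i0 + s.size] = np.where(
                s < rise,
                0.5 * (1.0 - np.cos(np.pi * s / rise)),
                0.5 * (1.0 + np.cos(np.pi * (s - rise) / (w - rise))),
            )
    return x


def generate_fsr_signals(
    events: GaitEvents, config: SynthConfig, duration_s: float | None = None
) -> Recording:
    """FSR channels: smooth unimodal loading per stance, zero in swing.

    Heel-channel onsets coincide with the event times to ±1 sample; the
    metatarsal and toe channels are plausible filler (delayed, scaled
    copies) since only the heels are used downstream.  Amplitudes are
    normalised 0–1.
    """
    rate = config.rate_hz
    all_t = np.concatenate([events.left_times, events.right_times])
    if all_t.size == 0:
        n = int(round((duration_s or 1.0) * rate))
        labels = tuple(c for c in DEFAULT_CHANNELS if c.startswith("FSR"))
        return Recording(np.zeros((n, len(labels))), rate, labels)
    if duration_s is None:
        duration_s = float(all_t.max()) + 1.5
    n = int(round(duration_s * rate))

    chans = {}
    for side, times in (("L", events.left_times), ("R", events.right_times)):
        if times.size > 1:
            gaps = np.diff(np.sort(times))
            stance = config.stance_frac * np.append(gaps, gaps[-1])
        else:
            stance = np.full(times.shape, config.stance_frac * 1.1)
        # FSR loading cannot be arbitrarily brief; implausibly close strikes
        # then produce overlapping stances and are rejected downstream
        stance = np.maximum(stance, 0.25)
        stance_n = np.maximum(np.round(stance * rate).astype(int), 2)
        heel = _heel_channel(times, n, rate, stance_n)
        chans[f"FSR_{side}_heel"] = heel
        # filler forefoot channels: delayed, attenuated loading
        delay = int(round(0.15 * rate * float(np.mean(stance)))) if times.size else 0
        fore = np.roll(heel, delay)
        fore[:delay] = 0.0
        chans[f"FSR_{side}_mt1"] = 0.8 * fore
        chans[f"FSR_{side}_mt5"] = 0.6 * fore
        chans[f"FSR_{side}_toe"] = 0.5 * np.roll(fore, delay)
        chans[f"FSR_{side}_toe"][:delay] = 0.0

    labels = tuple(c for c in DEFAULT_CHANNELS if c.startswith("FSR"))
    samples = np.column_stack([chans[c] for c in labels])
    return Recording(samples, rate, labels)


def _speed_gain_curve(events: GaitEvents, config: SynthConfig, t: np.ndarray) -> np.ndarray:
    if events.left_speeds is None or events.left_times.size == 0:
        return np.ones_like(t)
    v = np.interp(t, events.left_times, events.left_speeds)
    return 1.0 + config.speed_gain * (v - float(events.left_speeds.min()))


def true_envelope(
    events: GaitEvents,
    kernel: GroundTruthKernel,
    config: SynthConfig,
    muscle_side: str,
    duration_s: float,
) -> np.ndarray:
    """Noise-free envelope: (triggering heel signal ⊛ kernel) x speed gain."""
    fsr = generate_fsr_signals(events, config, duration_s)
    trig_side = {"CH": {"L": "R", "R": "L"}, "IH": {"L": "L", "R": "R"}}[kernel.foot][muscle_side]
    heel = fsr.channel(f"FSR_{trig_side}_heel")
    env = np.convolve(heel, kernel.coefficients)[: heel.size] / config.rate_hz
    t = np.arange(heel.size) / config.rate_hz
    return env * _speed_gain_curve(events, config, t)


def generate_emg(
    events: GaitEvents,
    kernels: list[GroundTruthKernel],
    config: SynthConfig,
    duration_s: float | None = None,
    sides: tuple[str, ...] = ("L", "R"),
) -> Recording:
    """Raw EMG whose linear envelope realises the ground-truth kernels.

    Each channel is unit-RMS band-limited Gaussian carrier noise multiplied
    by the noise-free envelope (plus a noise floor = envelope peak / SNR).
    The carrier is pre-scaled so that rectify-and-smooth conditioning
    recovers the modulating envelope with unit gain.
    """
    from scipy import signal as sp_signal

    rate = config.rate_hz
    all_t = np.concatenate([events.left_times, events.right_times])
    if duration_s is None:
        duration_s = (float(all_t.max()) + 1.5) if all_t.size else 1.0
    n = int(round(duration_s * rate))
    nominal_stride = float(stride_duration(1.25, config))
    for k in kernels:
        if k.duration_s > 2 * nominal_stride:
            raise ValueError(f"kernel {k.muscle}/{k.foot} longer than two strides")

    rng = config.rng(_STREAM_EMG)
    lo, hi = config.carrier_band_hz
    sos = sp_signal.butter(4, [lo, min(hi, 0.995 * rate / 2)], btype="band", fs=rate, output="sos")

    labels = tuple(c for c in DEFAULT_CHANNELS if c.startswith("EMG"))
    cols = []
    for label in labels:
        _, side, mus = label.split("_")
        env = np.zeros(n)
        for k in kernels:
            if k.muscle == mus:
                env += true_envelope(events, k, config, side, duration_s)[:n]
        floor = (env.max() / config.envelope_snr) if env.max() > 0 else 1e-3
        carrier = sp_signal.sosfilt(sos, rng.standard_normal(n))
        carrier /= np.sqrt(np.mean(carrier**2))
        # E|N(0,1)| = sqrt(2/pi); pre-scale so the conditioned envelope has unit gain
        carrier *= np.sqrt(np.pi / 2.0)
        cols.append(carrier * (env + floor))
    return Recording(np.column_stack(cols), rate, labels)


def default_kernels(config: SynthConfig, include_ta: bool = False) -> list[GroundTruthKernel]:
    """Physiologically-shaped ground-truth kernels, one nominal stride long.

    Built from the same critically-damped twitch primitive used by the
    fitting stage: RF carries an early (hip-flexion) and a terminal-swing
    (knee-extension) burst after contralateral contact; BF an
    ipsilateral-contact stance burst (hip extension) and a contralateral
    knee-flexion burst; LG a contralateral knee-flexion burst.  Amplitudes
    are arbitrary envelope units.
    """
    rate = config.rate_hz
    t_stride = float(stride_duration(1.25, config))
    t_ms = np.arange(int(round(t_stride * rate))) * 1000.0 / rate

    def bump(a, tau, t0):
        return a * model_curve(CurveParams(1.0, tau, tau, t0), t_ms)

    # burst widths (tau ~ 120-130 ms) match the breadth of gait activation
    # envelopes and keep the kernels inside the 6 Hz envelope-conditioning
    # band, which is what makes them identifiable from conditioned EMG
    kernels = [
        GroundTruthKernel("RF", "CH", bump(1.0, 120, 60) + bump(0.8, 100, 500), rate),
        GroundTruthKernel("BF", "IH", bump(1.0, 130, 60), rate),
        GroundTruthKernel("BF", "CH", bump(0.7, 130, 100), rate),
        GroundTruthKernel("LG", "CH", bump(0.6, 120, 140), rate),
    ]
    if include_ta:
        kernels.append(GroundTruthKernel("TA", "IH", bump(0.3, 120, 60), rate))
    return kernels


def generate_recording(
    profile: SpeedProfile,
    config: SynthConfig,
    kernels: list[GroundTruthKernel] | None = None,
) -> tuple[Recording, GaitEvents, list[GroundTruthKernel]]:
    """Full 16-channel synthetic recording (8 EMG + 8 FSR)."""
    if kernels is None:
        kernels = default_kernels(config)
    events = generate_gait_events(profile, config)
    duration = float(
        np.concatenate([events.left_times, events.right_times]).max()
    ) + 1.5
    fsr = generate_fsr_signals(events, config, duration)
    emg = generate_emg(events, kernels, config, duration)
    samples = np.column_stack([emg.samples, fsr.samples])
    rec = Recording(samples, config.rate_hz, tuple(emg.channels) + tuple(fsr.channels))
    return rec, events, kernels


def write_fixture(
    rec: Recording,
    events: GaitEvents,
    kernels: list[GroundTruthKernel],
    outdir: str | Path,
    config: SynthConfig | None = None,
) -> dict[str, Path]:
    """Write a recording plus a ground-truth sidecar; byte-deterministic.

    ``recording.csv`` holds the 16-channel matrix (documented column
    order); ``truth.json`` holds events, kernels and the generator config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec_path = write_recording(rec, outdir / "recording.csv")
    truth = {
        "rate_hz": rec.rate_hz,
        "left_times_s": [round(float(t), 9) for t in events.left_times],
        "right_times_s": [round(float(t), 9) for t in events.right_times],
        "kernels": [
            {
                "muscle": k.muscle,
                "foot": k.foot,
                "rate_hz": k.rate_hz,
                "coefficients": [round(float(c), 9) for c in k.coefficients],
            }
            for k in kernels
        ],
    }
    if config is not None:
        truth["config"] = asdict(config)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, sort_keys=True, indent=1))
    return {"recording": rec_path, "truth": truth_path}


def fixture_digest(paths: dict[str, Path]) -> str:
    """SHA-256 over the fixture files, for reproducibility checks."""
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(Path(paths[key]).read_bytes())
    return h.hexdigest()
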