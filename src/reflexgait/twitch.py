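"""Critically-damped muscle-twitch model and activation-curve fitting.

A muscle twitch is well described by the impulse response of a damped,
linear second-order system: a smooth, non-oscillatory rise and fall.  Each
joint-action segment extracted from the identified heel-contact-to-EMG
transfer functions is fitted with

    h(t) = 0                                        for t < T0
    h(t) = A * n(t - T0; tau1, tau2)                for t >= T0

where ``n`` is the bi-exponential ``exp(-t/tau2) - exp(-t/tau1)`` normalised
by its analytic peak value so that the fitted amplitude ``A`` *is* the peak
of the curve, and the critically-damped limit ``tau2 -> tau1 = tau`` is
``(t/tau) * exp(1 - t/tau)`` (also peaking at ``A``, at ``t = T0 + tau``).
``tau1`` and ``tau2`` play the role of rise and fall time constants and
``T0`` is the delay from the trigger (heel contact or hip extreme angle) to
contraction onset.  The bi-exponential is symmetric under swapping
``tau1 <-> tau2``; fitted pairs are therefore reported as found.

The fitted parameters are turned into the normalised motor activation
waveforms played out by the reflexive controller: sampled at the control
rate (200 Hz), clipped to non-negative values, peak-normalised to 1 V,
with a duration of one stride (1000 ms) for the hip and one step (500 ms)
for the knee.  Knee onset delays are zeroed because the knee's series
springs already impose an equivalent mechanical latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CurveParams",
    "FitResult",
    "MotorTransferFunction",
    "TFCharacteristics",
    "model_curve",
    "fit_curve",
    "finalize_motor_tf",
    "characterize",
    "stability_heuristic",
    "motor_tf_from_reference",
    "reference_motor_tf_set",
]

# relative tau1/tau2 difference below which the critical-limit branch is used
_CRITICAL_RTOL = 1e-9


@dataclass(frozen=True)
class CurveParams:
    """Twitch-curve parameters: amplitude and time constants in ms."""

    A: float
    tau1_ms: float
    tau2_ms: float
    T0_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.tau1_ms > 0 and self.tau2_ms > 0):
            raise ValueError("A, tau1 and tau2 must be positive")
        if self.T0_ms < 0:
            raise ValueError("T0 must be non-negative")


@dataclass(frozen=True)
class FitResult:
    params: CurveParams
    residual_rms: float
    converged: bool


@dataclass(frozen=True)
class MotorTransferFunction:
    """Finalized motor activation waveform at the control rate.

    ``samples`` are in normalised volts (0..1); index 0 is the trigger
    instant.  ``trigger`` names the sensory event that starts playback
    (CH = contralateral heel, IH = ipsilateral heel, AEA = hip anterior
    extreme angle).
    """

    joint: str  # "hip" | "knee"
    action: str  # "flexion" | "extension"
    samples: np.ndarray
    rate_hz: float = 200.0
    trigger: str = "CH"

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate_hz

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * 1000.0 / self.rate_hz


@dataclass(frozen=True)
class TFCharacteristics:
    """Activation-curve timing characteristics (ms).

    ``dT50_ms``: width between the first up-crossing and last down-crossing
    of 50% of the peak amplitude.  ``Tpeak_ms``: trigger-to-peak time.
    ``peak_at_boundary`` flags curves whose maximum sits on the first or
    last sample, where both quantities are unreliable.
    """

    dT50_ms: float
    Tpeak_ms: float
    peak_at_boundary: bool = False


def _biexp_peak(tau1: float, tau2: float) -> tuple[float, float]:
    """Peak time and value of exp(-t/tau2) - exp(-t/tau1)."""
    t_star = tau1 * tau2 * np.log(tau2 / tau1) / (tau2 - tau1)
    f_star = np.exp(-t_star / tau2) - np.exp(-t_star / tau1)
    return t_star, f_star


def model_curve(params: CurveParams, t_ms: np.ndarray) -> np.ndarray:
    """Evaluate the peak-normalised twitch model on a time axis in ms."""
    t = np.asarray(t_ms, dtype=float)
    tp = t - params.T0_ms
    out = np.zeros_like(tp)
    pos = tp > 0
    tau1, tau2 = params.tau1_ms, params.tau2_ms
    if abs(tau1 - tau2) <= _CRITICAL_RTOL * max(tau1, tau2):
        tau = 0.5 * (tau1 + tau2)
        x = tp[pos] / tau
        out[pos] = params.A * x * np.exp(1.0 - x)
    else:
        _, f_star = _biexp_peak(tau1, tau2)
        f = np.exp(-tp[pos] / tau2) - np.exp(-tp[pos] / tau1)
        out[pos] = params.A * f / f_star
    return out


_TAU_BOUNDS = (5.0, 500.0)
_T0_BOUNDS = (0.0, 500.0)


def fit_curve(
    t_ms: np.ndarray,
    values: np.ndarray,
    init: CurveParams | None = None,
    multistart: bool = True,
) -> FitResult:
    """Bounded least-squares fit of the twitch model to a segment.

    Neutral initialization is tau1 = tau2 = 50 ms, T0 = 0, A = segment peak.
    Because the model is symmetric in (tau1, tau2) the exactly-symmetric
    start is a saddle for asymmetric optima, so by default a small set of
    additional starts (asymmetric taus, onset-matched T0) is tried and the
    lowest-cost solution returned.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.size < 4:
        raise ValueError("need matching t/value arrays of length >= 4")
    peak = float(np.max(y))
    if peak <= 0:
        raise ValueError("segment has no positive values to fit")

    if init is None:
        init = CurveParams(A=peak, tau1_ms=50.0, tau2_ms=50.0, T0_ms=0.0)

    starts = [np.array([init.A, init.tau1_ms, init.tau2_ms, init.T0_ms])]
    if multistart:
        # asymmetric tau starts break the swap-symmetry saddle; an
        # onset-matched T0 start helps segments with long trigger delays
        t_peak = float(t[int(np.argmax(y))])
        t0_guess = float(np.clip(t_peak - 100.0, *_T0_BOUNDS))
        starts += [
            np.array([init.A, 25.0, 100.0, init.T0_ms]),
            np.array([init.A, 50.0, 50.0, t0_guess]),
            np.array([init.A, 25.0, 100.0, t0_guess]),
        ]

    lo = [1e-9 * peak, _TAU_BOUNDS[0], _TAU_BOUNDS[0], _T0_BOUNDS[0]]
    hi = [np.inf, _TAU_BOUNDS[1], _TAU_BOUNDS[1], _T0_BOUNDS[1]]

    def resid(p: np.ndarray) -> np.ndarray:
        return model_curve(CurveParams(*p), t) - y

    best = None
    for x0 in starts:
        sol = least_squares(
            resid, np.clip(x0, lo, hi), bounds=(lo, hi),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    params = CurveParams(*best.x)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return FitResult(params=params, residual_rms=rms, converged=bool(best.success))


_DURATION_MS = {"hip": 1000.0, "knee": 500.0}


def finalize_motor_tf(
    params: CurveParams,
    joint: str,
    trigger: str = "CH",
    action: str = "flexion",
    rate_hz: float = 200.0,
) -> MotorTransferFunction:
    """Finalize a fitted curve into a controller-ready activation waveform.

    Hip waveforms last one stride (1000 ms), knee waveforms one step
    (500 ms); the knee delay constant is forced to zero.  Negative values
    are clipped and the peak normalised to 1.
    """
    if joint not in _DURATION_MS:
        raise ValueError(f"joint must be 'hip' or 'knee', got {joint!r}")
    if joint == "knee":
        params = CurveParams(params.A, params.tau1_ms, params.tau2_ms, 0.0)
    n = int(round(_DURATION_MS[joint] * rate_hz / 1000.0))
    t = np.arange(n) * 1000.0 / rate_hz
    y = np.clip(model_curve(params, t), 0.0, None)
    peak = y.max()
    if peak <= 0:
        raise ValueError("finalized curve is identically zero")
    return MotorTransferFunction(
        joint=joint, action=action, samples=y / peak, rate_hz=rate_hz, trigger=trigger
    )


def _interp_crossing(t0, y0, t1, y1, level):
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def characterize(tf: MotorTransferFunction | np.ndarray, rate_hz: float | None = None) -> TFCharacteristics:
    """Timing characteristics of an activation curve.

    dT50 is measured between the first up-crossing and the last
    down-crossing of half the peak amplitude, with linear interpolation
    between samples; Tpeak is the trigger-to-peak time (trigger at t = 0).
    """
    if isinstance(tf, MotorTransferFunction):
        y = tf.samples
        rate = tf.rate_hz
    else:
        y = np.asarray(tf, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for a bare array")
        rate = rate_hz
    if y.size < 2:
        raise ValueError("curve too short to characterise")
    dt_ms = 1000.0 / rate
    t = np.arange(y.size) * dt_ms
    ipk = int(np.argmax(y))
    boundary = ipk in (0, y.size - 1)
    half = 0.5 * y[ipk]

    above = y >= half
    # first up-crossing
    if above[0]:
        t_rise = t[0]
    else:
        i = int(np.argmax(above))  # first True
        t_rise = _interp_crossing(t[i - 1], y[i - 1], t[i], y[i], half)
    # last down-crossing
    if above[-1]:
        t_fall = t[-1]
    else:
        j = y.size - 1 - int(np.argmax(above[::-1]))  # last True
        t_fall = _interp_crossing(t[j], y[j], t[j + 1], y[j + 1], half)
    dT50 = float(t_fall - t_rise)
    if dT50 <= 0:  # single-sample peak: fall back to one sample interval
        dT50 = dt_ms
    return TFCharacteristics(dT50_ms=dT50, Tpeak_ms=float(t[ipk]), peak_at_boundary=boundary)


def stability_heuristic(
    flexor: TFCharacteristics, extensor: TFCharacteristics
) -> tuple[bool, float]:
    """Hip-timing stability rule: extensor activation must outlast flexor.

    Returns ``(verdict, margin_ms)`` with ``verdict = ext.dT50 > flex.dT50``
    and ``margin = ext.dT50 - flex.dT50``.  The rule is a heuristic: the
    stance hip needs a long enough extension drive to carry the body over
    the swing leg, but the published outcomes include exceptions in both
    directions.
    """
    margin = extensor.dT50_ms - flexor.dT50_ms
    return margin > 0, float(margin)


def motor_tf_from_reference(
    set_id: str, joint: str, action: str, rate_hz: float = 200.0
) -> MotorTransferFunction:
    """Build a finalized activation waveform from a published parameter set."""
    from . import reference

    table = reference.HIP_CURVE_PARAMS if joint == "hip" else reference.KNEE_CURVE_PARAMS
    tau1, tau2, t0 = table[set_id][action]
    trigger = {
        ("hip", "flexion"): "CH",
        ("hip", "extension"): "IH",
        ("knee", "flexion"): "CH",
        ("knee", "extension"): "AEA",
    }[(joint, action)]
    params = CurveParams(A=1.0, tau1_ms=tau1, tau2_ms=tau2, T0_ms=t0)
    return finalize_motor_tf(params, joint, trigger=trigger, action=action, rate_hz=rate_hz)


def reference_motor_tf_set(set_id: str, rate_hz: float = 200.0) -> dict[str, MotorTransferFunction]:
    """All four activation waveforms of a published set, keyed by wiring.

    Keys: ``hip_flexion`` (CH-triggered), ``hip_extension`` (IH),
    ``knee_flexion`` (CH), ``knee_extension`` (AEA).
    """
    return {
        f"{joint}_{action}": motor_tf_from_reference(set_id, joint, action, rate_hz)
        for joint in ("hip", "knee")
        for action in ("flexion", "extension")
    }
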