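"""LMS identification of heel-contact -> muscle-envelope transfer functions.

An adaptive FIR filter of length two strides is trained sample-by-sample:
the estimate is the convolution of the coefficients with the heel FSR
input, the error is the difference from the desired EMG envelope, and each
coefficient update applies the error-weighted input with learning rate mu
(normalised by instantaneous input power by default, for stability across
FSR amplitude scales).  Training runs a fixed number of full passes over
the record (default 100, where the filter has converged).  The identified
response is then truncated to one stride with a half-Hanning taper so that
exactly the coefficients generating a one-stride activation after heel
contact remain.

Envelopes are band-limited to a few Hz, so identification is normally run
on decimated signals (see :func:`decimate_pair`); the filter length in
samples adapts to the working rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "ImpulseResponse",
    "PredictionResult",
    "LMSDivergence",
    "lms_identify",
    "apply_half_hanning",
    "predict",
    "final_mse",
    "wiener_solution",
    "decimate_pair",
    "nrmse",
]


class LMSDivergence(RuntimeError):
    """The adaptive filter diverged (MSE became non-finite)."""


@dataclass
class ImpulseResponse:
    """Identified FIR coefficients plus the training diagnostics."""

    h: np.ndarray
    rate_hz: float
    stride_s: float
    mu: float
    iterations: int
    mse_trace: np.ndarray

    @property
    def final_mse(self) -> float:
        return float(self.mse_trace[-1])

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(len(self.h)) / self.rate_hz


@dataclass(frozen=True)
class PredictionResult:
    estimate: np.ndarray
    error: np.ndarray


def lms_identify(
    x: np.ndarray,
    d: np.ndarray,
    rate_hz: float,
    stride_s: float,
    mu: float = 0.01,
    iterations: int = 100,
    normalized: bool = True,
    h0: np.ndarray | None = None,
) -> ImpulseResponse:
    """Identify the FIR response from input ``x`` to desired ``d``.

    The filter length is two mean stride durations.  ``mu`` is the raw
    learning rate; with ``normalized=True`` (default) each update is scaled
    by the instantaneous input power, making convergence insensitive to the
    FSR amplitude scale.  ``mu = 0`` leaves the initialization untouched.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    if x.shape != d.shape or x.ndim != 1:
        raise ValueError("x and d must be 1-D arrays of equal length")
    if stride_s <= 0:
        raise ValueError("stride duration must be positive")
    m = int(round(2 * stride_s * rate_hz))
    if m < 1 or m > x.size:
        raise ValueError("filter length (two strides) must fit inside the record")

    # reversed-coefficient layout so each step uses a contiguous input slice
    hrev = np.zeros(m) if h0 is None else np.asarray(h0, dtype=float)[::-1].copy()
    xpad = np.concatenate([np.zeros(m - 1), x])
    n = x.size
    # power-normalisation floor: a fraction of the average window energy, so
    # near-empty windows (record edges, swing-only spans) cannot blow up the
    # step size; proportional to input power, preserving scale covariance
    eps = 0.01 * m * float(np.mean(x**2)) + 1e-300
    mse = np.empty(iterations)
    with np.errstate(over="ignore", invalid="ignore"):  # divergence is caught below
        for it in range(iterations):
            sq = 0.0
            for i in range(n):
                win = xpad[i : i + m]
                e = d[i] - hrev @ win
                sq += e * e
                if mu:
                    step = mu / (eps + win @ win) if normalized else mu
                    hrev += (step * e) * win
            mse[it] = sq / n
            if not np.isfinite(mse[it]):
                raise LMSDivergence(
                    f"MSE diverged at iteration {it} (mu={mu}, normalized={normalized}); "
                    "reduce the learning rate"
                )
    return ImpulseResponse(
        h=hrev[::-1].copy(), rate_hz=rate_hz, stride_s=stride_s, mu=mu,
        iterations=iterations, mse_trace=mse,
    )


def apply_half_hanning(
    resp: ImpulseResponse | np.ndarray,
    stride_s: float | None = None,
    rate_hz: float | None = None,
    mode: str = "multiply",
) -> np.ndarray:
    """Truncate a two-stride response to one stride with a half-Hanning taper.

    ``mode="multiply"`` (default) keeps the first stride of coefficients and
    multiplies the second half of it by a decaying half-Hanning window so
    the tail goes smoothly to zero — this *selects* the coefficients that
    generate a one-stride activation after a heel contact.  ``mode=
    "convolve"`` is the literal alternative reading (convolution with a
    half-Hanning kernel), which smooths rather than selects; it is provided
    for comparison.
    """
    if isinstance(resp, ImpulseResponse):
        h, stride_s, rate_hz = resp.h, resp.stride_s, resp.rate_hz
    else:
        h = np.asarray(resp, dtype=float)
        if stride_s is None or rate_hz is None:
            raise ValueError("stride_s and rate_hz required for a bare array")
    m = int(round(stride_s * rate_hz))
    if m > h.size:
        raise ValueError("stride is longer than the identified response")
    if mode == "multiply":
        out = h[:m].copy()
        tail = m - m // 2
        out[m // 2 :] *= np.hanning(2 * tail)[tail:]
        return out
    if mode == "convolve":
        tail = m - m // 2
        w = np.hanning(2 * tail)[tail:]
        w /= w.sum()
        return np.convolve(h, w)[:m]
    raise ValueError(f"unknown mode {mode!r}")


def predict(h: np.ndarray, x: np.ndarray, d: np.ndarray | None = None) -> PredictionResult:
    """Filter output y = h ⊛ x and, when ``d`` is given, the error d − y."""
    h = np.asarray(h, dtype=float)
    x = np.asarray(x, dtype=float)
    y = sp_signal.fftconvolve(x, h)[: x.size]
    if d is None:
        err = np.zeros_like(y)
    else:
        d = np.asarray(d, dtype=float)
        if d.shape != x.shape:
            raise ValueError("d must match x in length")
        err = d - y
    return PredictionResult(estimate=y, error=err)


def final_mse(h: np.ndarray, x: np.ndarray, d: np.ndarray) -> float:
    """Mean squared residual of the filter against the desired signal."""
    return float(np.mean(predict(h, x, d).error ** 2))


def wiener_solution(x: np.ndarray, d: np.ndarray, m: int, rcond: float = 1e-2) -> np.ndarray:
    """Batch least-squares FIR solution — the independent LMS oracle.

    Solves ``min ||X h - d||`` where X is the convolution matrix of ``x``
    with ``m`` taps, via a truncated-SVD pseudo-inverse: smooth contact
    pulses barely excite the high-frequency filter directions, so those
    directions are set to zero (``rcond`` is the relative singular-value
    cutoff) rather than fitted to measurement noise — matching what LMS
    trained from zero initialization leaves untouched.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    n = x.size
    xpad = np.concatenate([np.zeros(m - 1), x])
    cols = np.lib.stride_tricks.sliding_window_view(xpad, m)[:n, ::-1]
    h, *_ = np.linalg.lstsq(cols, d, rcond=rcond)
    return h


def decimate_pair(
    x: np.ndarray, d: np.ndarray, rate_hz: float, target_hz: float = 100.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Anti-aliased decimation of an (input, envelope) pair for identification."""
    q = int(round(rate_hz / target_hz))
    if q <= 1:
        return np.asarray(x, float), np.asarray(d, float), rate_hz
    xd = sp_signal.decimate(np.asarray(x, float), q, ftype="fir", zero_phase=True)
    dd = sp_signal.decimate(np.asarray(d, float), q, ftype="fir", zero_phase=True)
    return xd, dd, rate_hz / q


def nrmse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square error normalised by the RMS of the truth."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n = min(estimate.size, truth.size)
    a, b = estimate[:n], truth[:n]
    denom = np.sqrt(np.mean(b**2))
    if denom == 0:
        raise ValueError("truth signal is identically zero")
    return float(np.sqrt(np.mean((a - b) ** 2)) / denom)
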