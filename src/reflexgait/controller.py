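"""Reflexive walking controller: sensor-triggered activation playback.

The controller is purely reactive — no central pattern generator, no
trajectory planning, no internal oscillator.  Ground-contact switches emit
a unit impulse on each 0->1 transition; the hip anterior extreme angle
(AEA) emits an impulse when the hip flexion angle up-crosses its
threshold.  Each motor drive is the convolution of its trigger impulse
train with the corresponding motor transfer function:

* hip flexion   <- contralateral ground contact
* hip extension <- ipsilateral ground contact
* knee flexion  <- contralateral ground contact
* knee extension<- ipsilateral hip AEA

Overlapping playbacks from repeated triggers are summed (the drive path is
linear and time-invariant).  Drives are limited by a soft extreme-angle
guard, multiplied by per-motor gains and the motor-amplifier gain (2.3),
and clipped at the output rail.  With all-zero sensor streams the output
is identically zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .twitch import MotorTransferFunction

__all__ = [
    "ControllerConfig",
    "TriggerEvents",
    "MotorCommand",
    "ReflexController",
    "derive_triggers",
    "motor_drive",
    "extreme_angle_guard",
    "apply_gain",
]

log = logging.getLogger("reflexgait")

LEGS = ("left", "right")
CHANNELS = ("hip_flexion", "hip_extension", "knee_flexion", "knee_extension")


@dataclass(frozen=True)
class ControllerConfig:
    """Gains, thresholds and rates of the reflexive controller.

    Extreme angles and gains are artifact defaults tuned for the surrogate
    plant (the physical robot's hand-tuned values are not reproduced here).
    Angles are in degrees; hip angle is measured from vertical, positive
    forward (flexion); knee angle is 0 when straight, positive in flexion.
    """

    rate_hz: float = 200.0
    gain_hip: float = 1.0
    gain_knee: float = 1.0
    amplifier_gain: float = 2.3
    rail_v: float = 4.0
    aea_deg: float = 12.0  # hip anterior extreme angle triggering knee extension
    hip_max_deg: float = 32.0  # extreme flexion angle
    hip_min_deg: float = -32.0  # extreme extension angle
    knee_max_deg: float = 65.0
    guard_band_deg: float = 5.0  # soft ramp to zero over the last degrees

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    def gain(self, channel: str) -> float:
        return self.gain_hip if channel.startswith("hip") else self.gain_knee


@dataclass
class TriggerEvents:
    """Impulse trains (one sample per tick): contact rising edges and AEA."""

    contact_left: np.ndarray
    contact_right: np.ndarray
    aea_left: np.ndarray
    aea_right: np.ndarray

    def for_leg(self, leg: str) -> dict[str, np.ndarray]:
        ipsi = self.contact_left if leg == "left" else self.contact_right
        contra = self.contact_right if leg == "left" else self.contact_left
        aea = self.aea_left if leg == "left" else self.aea_right
        return {"CH": contra, "IH": ipsi, "AEA": aea}


@dataclass(frozen=True)
class MotorCommand:
    """One control tick's outputs, keyed '<leg>_<channel>'.

    ``U`` is the raw convolution drive, ``gamma`` the extreme-angle guard
    factor and ``V`` the gained, guarded, rail-clipped output voltage.
    """

    U: dict[str, float]
    gamma: dict[str, float]
    V: dict[str, float]

    def net_hip(self, leg: str) -> float:
        return self.V[f"{leg}_hip_flexion"] - self.V[f"{leg}_hip_extension"]

    def net_knee(self, leg: str) -> float:
        return self.V[f"{leg}_knee_flexion"] - self.V[f"{leg}_knee_extension"]


def _rising_edges(state: np.ndarray) -> np.ndarray:
    s = np.asarray(state, dtype=float) > 0.5
    imp = np.zeros(s.size)
    imp[1:][s[1:] & ~s[:-1]] = 1.0  # 0->1 transitions only; constant contact is silent
    return imp


def derive_triggers(
    contact_left: np.ndarray,
    contact_right: np.ndarray,
    hip_left: np.ndarray,
    hip_right: np.ndarray,
    config: ControllerConfig,
) -> TriggerEvents:
    """Impulse trains from contact states and hip angles (offline form)."""
    hl = np.asarray(hip_left, dtype=float)
    hr = np.asarray(hip_right, dtype=float)

    def aea(h: np.ndarray) -> np.ndarray:
        above = h >= config.aea_deg
        imp = np.zeros(h.size)
        imp[1:][above[1:] & ~above[:-1]] = 1.0
        return imp

    return TriggerEvents(
        contact_left=_rising_edges(contact_left),
        contact_right=_rising_edges(contact_right),
        aea_left=aea(hl),
        aea_right=aea(hr),
    )


def motor_drive(
    triggers: TriggerEvents,
    tfs: dict[str, MotorTransferFunction],
    config: ControllerConfig,
) -> dict[str, np.ndarray]:
    """Offline drive signals U: trigger train ⊛ transfer function per motor."""
    for ch in CHANNELS:
        if ch not in tfs:
            raise ValueError(f"no transfer function configured for {ch}")
    n = triggers.contact_left.size
    out: dict[str, np.ndarray] = {}
    for leg in LEGS:
        trains = triggers.for_leg(leg)
        for ch in CHANNELS:
            train = trains[tfs[ch].trigger]
            out[f"{leg}_{ch}"] = np.convolve(train, tfs[ch].samples)[:n]
    return out


def extreme_angle_guard(
    angle_deg: float, threshold_deg: float, direction: str, band_deg: float = 5.0
) -> float:
    """Soft limiter Γ ∈ [0, 1] as a joint approaches its extreme angle.

    Γ = 1 well inside the range, ramps linearly to 0 over the final
    ``band_deg`` before the threshold, and stays 0 beyond it.
    ``direction`` is "increasing" when the guarded motion grows the angle.
    """
    if direction == "increasing":
        margin = threshold_deg - angle_deg
    elif direction == "decreasing":
        margin = angle_deg - threshold_deg
    else:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    return float(np.clip(margin / band_deg, 0.0, 1.0))


def apply_gain(u: float, gamma: float, channel_gain: float, config: ControllerConfig) -> float:
    """V = motor gain x amplifier gain x Γ·U, saturated at the output rail."""
    v = channel_gain * config.amplifier_gain * gamma * u
    return float(np.clip(v, -config.rail_v, config.rail_v))


class ReflexController:
    """Tick-by-tick reflexive controller with pending-playback state.

    The only internal state is the previous contact/AEA comparator values
    and the list of transfer-function playbacks still in flight — there is
    no clock-driven pattern.  Hip playbacks last 1000 ms, knee playbacks
    500 ms (the transfer-function durations).
    """

    def __init__(self, tfs: dict[str, MotorTransferFunction], config: ControllerConfig | None = None):
        self.config = config or ControllerConfig()
        for ch in CHANNELS:
            if ch not in tfs:
                raise ValueError(f"no transfer function configured for {ch}")
            if tfs[ch].rate_hz != self.config.rate_hz:
                raise ValueError("transfer functions must be sampled at the control rate")
        self.tfs = tfs
        self.reset()

    def reset(self) -> None:
        self._tick = 0
        self._prev_contact = {"left": False, "right": False}
        self._prev_above_aea = {"left": False, "right": False}
        # playbacks: list of (motor key, tf key, ticks elapsed)
        self._active: list[list] = []
        self._last_command = self._zero_command()

    def _zero_command(self) -> MotorCommand:
        zeros = {f"{leg}_{ch}": 0.0 for leg in LEGS for ch in CHANNELS}
        ones = {k: 1.0 for k in zeros}
        return MotorCommand(U=dict(zeros), gamma=ones, V=dict(zeros))

    def _start(self, leg: str, ch: str) -> None:
        self._active.append([f"{leg}_{ch}", ch, 0])

    def step(
        self,
        contact_left: bool,
        contact_right: bool,
        hip_left_deg: float,
        hip_right_deg: float,
        knee_left_deg: float,
        knee_right_deg: float,
    ) -> MotorCommand:
        """One control tick (5 ms at the default 200 Hz)."""
        cfg = self.config
        sensors = (hip_left_deg, hip_right_deg, knee_left_deg, knee_right_deg)
        if any(map(math.isnan, sensors)):
            log.warning("NaN sensor sample at tick %d; holding previous command", self._tick)
            self._tick += 1
            return self._last_command

        contact = {"left": bool(contact_left), "right": bool(contact_right)}
        hips = {"left": hip_left_deg, "right": hip_right_deg}
        knees = {"left": knee_left_deg, "right": knee_right_deg}

        for leg in LEGS:
            other = "right" if leg == "left" else "left"
            if contact[leg] and not self._prev_contact[leg]:
                # ipsilateral contact: own extension; contralateral flexion
                self._start(leg, "hip_extension")
                self._start(other, "hip_flexion")
                self._start(other, "knee_flexion")
            above = hips[leg] >= cfg.aea_deg
            if above and not self._prev_above_aea[leg]:
                self._start(leg, "knee_extension")
            self._prev_contact[leg] = contact[leg]
            self._prev_above_aea[leg] = above

        U = {f"{leg}_{ch}": 0.0 for leg in LEGS for ch in CHANNELS}
        still = []
        for rec in self._active:
            key, ch, k = rec
            samples = self.tfs[ch].samples
            if k < samples.size:
                U[key] += float(samples[k])
                rec[2] += 1
                still.append(rec)
        self._active = still

        gamma, V = {}, {}
        for leg in LEGS:
            g = {
                "hip_flexion": extreme_angle_guard(hips[leg], cfg.hip_max_deg, "increasing", cfg.guard_band_deg),
                "hip_extension": extreme_angle_guard(hips[leg], cfg.hip_min_deg, "decreasing", cfg.guard_band_deg),
                "knee_flexion": extreme_angle_guard(knees[leg], cfg.knee_max_deg, "increasing", cfg.guard_band_deg),
                "knee_extension": extreme_angle_guard(knees[leg], 0.0, "decreasing", cfg.guard_band_deg),
            }
            for ch in CHANNELS:
                key = f"{leg}_{ch}"
                gamma[key] = g[ch]
                V[key] = apply_gain(U[key], g[ch], cfg.gain(ch), cfg)

        self._tick += 1
        self._last_command = MotorCommand(U=U, gamma=gamma, V=V)
        return self._last_command
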