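"""Surrogate planar biped plant for closed-loop controller evaluation.

This is an explicit stand-in for the physical robot, not a
dynamics-faithful model: joints follow the motor voltages through
first-order lags (the knee through an extra spring lag), ground contact is
kinematic (the swing foot lands when its geometric height reaches the
ground with the leg protracted), and between playbacks the joints relax
monotonically toward neutral — the passive-dynamic phase analog.  It
closes the sensor-motor loop so that gait emergence, stability tendencies
and limit-cycle behaviour of the reflexive controller can be studied; it
does not predict which specific published parameter sets walk on hardware.

Conventions: hip angle from vertical, positive forward (flexion); knee
angle 0 when straight (a hard "kneecap" stop prevents hyperextension),
positive in flexion.  The legs are unit-mass-free kinematic chains of two
equal segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import ReflexController

__all__ = ["PlantConfig", "WalkerState", "SimResult", "simulate", "gait_metrics", "phase_portrait"]

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class PlantConfig:
    """Geometry, lags and safety thresholds of the surrogate plant."""

    leg_length_m: float = 0.3  # hip axis to foot, both segments equal
    #: passive forward pivot of the body over the planted foot, the
    #: passive-dynamic walking phase analog: while the gait has momentum the
    #: stance hip extends at this rate even with its motor off, so the body
    #: keeps falling forward; without any motor activity there is no
    #: momentum and the walker stands still
    pivot_rate_deg_s: float = 30.0
    momentum_tau_s: float = 0.25  # build-up/decay of the forward momentum gate
    hip_tau_s: float = 0.12  # first-order motor lag, hip (unloaded/swing)
    #: the stance hip carries the body weight and responds this many times
    #: slower than the free swing hip
    stance_load_factor: float = 2.5
    knee_motor_tau_s: float = 0.05  # knee motor lag
    knee_spring_tau_s: float = 0.06  # spring transmission lag motor->joint
    hip_deg_per_v: float = 20.0  # steady-state hip angle per net volt
    knee_deg_per_v: float = 24.0  # steady-state knee motor angle per net volt
    knee_max_deg: float = 70.0
    min_swing_s: float = 0.15  # contact refractory after a step
    max_step_s: float = 2.5  # halt if no step happens for this long
    scuff_knee_deg: float = 20.0  # touchdown with this much knee flexion = stumble
    min_protraction_deg: float = 5.0  # swing hip must lead by this to land
    fall_height_frac: float = 0.82  # fall if hip height < frac x leg length

    def __post_init__(self) -> None:
        if self.leg_length_m <= 0:
            raise ValueError("leg length must be positive")
        for tau in (self.hip_tau_s, self.knee_motor_tau_s, self.knee_spring_tau_s):
            if tau <= 0:
                raise ValueError("time constants must be positive")


@dataclass
class WalkerState:
    """Joint state of the surrogate biped at one control tick."""

    t: float = 0.0
    hip_deg: dict = field(default_factory=lambda: {"left": 0.0, "right": 0.0})
    knee_deg: dict = field(default_factory=lambda: {"left": 0.0, "right": 0.0})
    knee_motor_deg: dict = field(default_factory=lambda: {"left": 0.0, "right": 0.0})
    stance: str = "left"
    progress_m: float = 0.0


@dataclass
class SimResult:
    """Closed-loop trajectory plus the contact log."""

    t: np.ndarray
    hip_deg: dict[str, np.ndarray]
    knee_deg: dict[str, np.ndarray]
    v_net: dict[str, np.ndarray]
    contacts: dict[str, np.ndarray]  # contact event times per foot
    progress_m: float
    duration_s: float
    fell: bool
    halt_reason: str
    rate_hz: float

    @property
    def n_strides(self) -> int:
        """Completed strides of the reference (left) foot."""
        return max(len(self.contacts["left"]) - 1, 0)


def _foot_drop(leg_half: float, hip_deg: float, knee_deg: float) -> float:
    """Vertical drop from hip to foot for a two-segment leg."""
    th = hip_deg * _DEG
    return leg_half * (np.cos(th) + np.cos(th - knee_deg * _DEG))


def _foot_reach(leg_half: float, hip_deg: float, knee_deg: float) -> float:
    """Horizontal reach from hip to foot (positive forward)."""
    th = hip_deg * _DEG
    return leg_half * (np.sin(th) + np.sin(th - knee_deg * _DEG))


def simulate(
    controller: ReflexController,
    plant: PlantConfig | None = None,
    duration_s: float = 30.0,
    seed: int = 0,
    initial_split_deg: float = 16.0,
) -> SimResult:
    """Run the reflexive controller closed-loop on the surrogate plant.

    The walker starts in a split stance (left foot planted, hips at
    ±``initial_split_deg`` with ~1 degree of seeded jitter) and the initial
    left contact fires the first reflex chain.  Deterministic for a fixed
    seed.  The run halts early on a fall (hip below the height threshold or
    a scuffed touchdown) or if no step occurs within ``max_step_s``.
    """
    plant = plant or PlantConfig()
    cfg = controller.config
    controller.reset()
    rng = np.random.default_rng(seed)
    dt = cfg.dt
    half = plant.leg_length_m / 2.0

    st = WalkerState()
    st.hip_deg["left"] = initial_split_deg + rng.normal(0.0, 1.0)
    st.hip_deg["right"] = -initial_split_deg + rng.normal(0.0, 1.0)
    st.stance = "left"
    contact = {"left": True, "right": False}
    last_step_t = 0.0
    momentum = 0.0  # gates the passive pivot; grows only under motor drive

    n = int(round(duration_s / dt))
    t_arr = np.arange(n) * dt
    hip_log = {leg: np.zeros(n) for leg in ("left", "right")}
    knee_log = {leg: np.zeros(n) for leg in ("left", "right")}
    v_log = {f"{leg}_{j}": np.zeros(n) for leg in ("left", "right") for j in ("hip", "knee")}
    contacts = {"left": [0.0], "right": []}
    fell, halt = False, "completed"

    for i in range(n):
        st.t = t_arr[i]
        cmd = controller.step(
            contact["left"], contact["right"],
            st.hip_deg["left"], st.hip_deg["right"],
            st.knee_deg["left"], st.knee_deg["right"],
        )
        drive = sum(abs(v) for v in cmd.V.values())
        momentum += dt / plant.momentum_tau_s * ((1.0 if drive > 0.05 else 0.0) - momentum)

        for leg in ("left", "right"):
            v_hip = cmd.net_hip(leg)
            v_knee = cmd.net_knee(leg)
            v_log[f"{leg}_hip"][i] = v_hip
            v_log[f"{leg}_knee"][i] = v_knee
            # hip: first-order toward the commanded angle (0 when idle),
            # plus the passive forward pivot on the stance side
            hip_cmd = plant.hip_deg_per_v * v_hip
            tau_eff = plant.hip_tau_s * (plant.stance_load_factor if leg == st.stance else 1.0)
            st.hip_deg[leg] += dt / tau_eff * (hip_cmd - st.hip_deg[leg])
            if leg == st.stance:
                st.hip_deg[leg] -= plant.pivot_rate_deg_s * momentum * dt
            # knee: motor lag, then spring transmission lag, kneecap stop at 0
            knee_cmd = plant.knee_deg_per_v * v_knee
            m = st.knee_motor_deg[leg]
            m += dt / plant.knee_motor_tau_s * (knee_cmd - m)
            st.knee_motor_deg[leg] = m
            k = st.knee_deg[leg]
            k += dt / plant.knee_spring_tau_s * (m - k)
            st.knee_deg[leg] = float(np.clip(k, 0.0, plant.knee_max_deg))
            hip_log[leg][i] = st.hip_deg[leg]
            knee_log[leg][i] = st.knee_deg[leg]

        stance, swing = st.stance, ("right" if st.stance == "left" else "left")
        y_st = _foot_drop(half, st.hip_deg[stance], st.knee_deg[stance])
        y_sw = _foot_drop(half, st.hip_deg[swing], st.knee_deg[swing])

        if y_st < plant.fall_height_frac * plant.leg_length_m:
            fell, halt = True, "fell: hip height below threshold"
            break
        if st.t - last_step_t > plant.max_step_s:
            halt = "halted: no step within the step timeout"
            break

        protracted = st.hip_deg[swing] - st.hip_deg[stance] >= plant.min_protraction_deg
        landed = y_sw >= y_st and st.hip_deg[swing] > 0
        if landed and (st.t - last_step_t) >= plant.min_swing_s:
            if not protracted:
                fell, halt = True, "fell: foot landed without protraction"
                break
            if st.knee_deg[swing] > plant.scuff_knee_deg:
                fell, halt = True, "fell: scuffed touchdown (knee still flexed)"
                break
            # step: progress advances by the distance between the feet
            st.progress_m += _foot_reach(half, st.hip_deg[swing], st.knee_deg[swing]) - _foot_reach(
                half, st.hip_deg[stance], st.knee_deg[stance]
            )
            st.stance = swing
            contact = {"left": swing == "left", "right": swing == "right"}
            contacts[swing].append(float(st.t))
            last_step_t = st.t
        else:
            contact = {stance: True, swing: False}

    n_done = i + 1 if n else 0
    return SimResult(
        t=t_arr[:n_done],
        hip_deg={k: v[:n_done] for k, v in hip_log.items()},
        knee_deg={k: v[:n_done] for k, v in knee_log.items()},
        v_net={k: v[:n_done] for k, v in v_log.items()},
        contacts={k: np.asarray(v) for k, v in contacts.items()},
        progress_m=st.progress_m,
        duration_s=float(t_arr[n_done - 1] + dt) if n_done else 0.0,
        fell=fell,
        halt_reason=halt,
        rate_hz=cfg.rate_hz,
    )


def gait_metrics(result: SimResult, plant: PlantConfig | None = None) -> dict[str, float]:
    """Stride length/duration, speed and leg-length-relative speed."""
    plant = plant or PlantConfig()
    left = result.contacts["left"]
    if len(left) < 3:
        raise ValueError("need at least two completed strides for gait metrics")
    stride_durations = np.diff(left)
    duration = float(left[-1] - left[0])
    speed = result.progress_m / result.duration_s
    return {
        "n_strides": float(len(left) - 1),
        "stride_duration_s": float(stride_durations.mean()),
        "stride_length_m": float(speed * stride_durations.mean()),
        "speed_m_s": float(speed),
        "relative_speed_leg_per_s": float(speed / plant.leg_length_m),
    }


def phase_portrait(
    knee_deg: np.ndarray, rate_hz: float, section_times: np.ndarray | None = None
) -> dict[str, np.ndarray | float]:
    """Knee phase plane (angle vs angular velocity) and limit-cycle dispersion.

    Velocity is taken by central differences.  When ``section_times`` (heel
    strikes) are given, the trajectory is sampled on that Poincaré section
    and the dispersion is the mean distance between successive section
    points, with each axis standardised by its spread — near zero for a
    settled limit cycle.
    """
    th = np.asarray(knee_deg, dtype=float)
    if th.size < 3:
        raise ValueError("need at least three samples")
    om = np.gradient(th) * rate_hz
    out: dict[str, np.ndarray | float] = {"angle_deg": th, "velocity_deg_s": om}
    if section_times is not None and len(section_times) >= 3:
        idx = np.clip(np.round(np.asarray(section_times) * rate_hz).astype(int), 0, th.size - 1)
        pts = np.column_stack([th[idx], om[idx]])
        scale = pts.std(axis=0)
        floor = 1e-9 * max(float(np.abs(pts).max()), 1.0)
        scale[scale <= floor] = 1.0
        z = pts / scale
        out["section_points"] = pts
        out["dispersion"] = float(np.mean(np.linalg.norm(np.diff(z, axis=0), axis=1)))
    return out
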