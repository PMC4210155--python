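"""Walk the surrogate biped closed-loop with a published transfer-function set.

The reflexive controller plays the four motor activation waveforms on
sensor triggers only (ground contact and hip extreme angle — no pattern
generator), and the surrogate planar plant closes the loop: joints follow
the voltages through first-order lags, the body pivots passively over the
stance foot, and the swing foot's kinematic touchdown fires the next
reflex chain.
"""

from reflexgait.controller import ControllerConfig, ReflexController
from reflexgait.twitch import reference_motor_tf_set
from reflexgait.walker import PlantConfig, gait_metrics, phase_portrait, simulate

plant = PlantConfig()
controller = ReflexController(reference_motor_tf_set("1B"), ControllerConfig())
result = simulate(controller, plant, duration_s=20.0, seed=1)

print(f"outcome: {result.halt_reason} (fell: {result.fell})")
metrics = gait_metrics(result, plant)
print(f"strides:        {metrics['n_strides']:.0f}")
print(f"stride duration {metrics['stride_duration_s']:.3f} s")
print(f"stride length   {metrics['stride_length_m']:.3f} m")
print(f"speed           {metrics['speed_m_s']:.3f} m/s "
      f"({metrics['relative_speed_leg_per_s']:.2f} leg lengths/s)")

portrait = phase_portrait(result.knee_deg["right"], result.rate_hz,
                          result.contacts["right"])
print(f"limit-cycle dispersion at heel strike: {portrait['dispersion']:.3f}")
# A sustained stride count with low Poincare dispersion means the purely
# reflexive loop settles into limit-cycle walking: each heel strike
# re-triggers the same activation pattern and the gait repeats.
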