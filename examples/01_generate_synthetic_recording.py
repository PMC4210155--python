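"""Generate a synthetic treadmill-walking recording with known ground truth.

Builds a pseudo-random belt-speed profile (increments of 0.05-0.1 m/s),
simulates alternating heel strikes at a speed-dependent cadence, and
synthesizes the 16-channel recording: 8 EMG channels whose envelopes are
heel-contact signals convolved with known muscle kernels, and 8 FSR
channels with smooth stance loading curves.
"""

from reflexgait.synthetic import SynthConfig, generate_recording, generate_speed_sequence, write_fixture

config = SynthConfig(seed=42)
profile = generate_speed_sequence(
    n_settings=10, speed_range=(0.9, 1.4), repeats=1, seed=42,
    strides_per_setting=10, config=config,
)
print(f"speed profile: {[f'{v:.2f}' for v, _ in profile.settings]} m/s "
      f"(range {profile.total_range:.2f} m/s)")

recording, events, kernels = generate_recording(profile, config)
print(f"recording: {recording.n_samples} samples x {len(recording.channels)} channels "
      f"at {recording.rate_hz:.0f} Hz ({recording.duration_s:.1f} s)")
print(f"strides: {len(events.left_times) - 1} left heel strikes, "
      f"{len(events.right_times)} right")
print(f"ground-truth kernels: {[(k.muscle, k.foot) for k in kernels]}")

paths = write_fixture(recording, events, kernels, "scratch/example_fixture", config)
print(f"written: {paths['recording']} plus truth sidecar {paths['truth']}")
# The sidecar stores the true kernels and event times, so every later stage
# (detection, identification, curve fitting) can be scored against truth.
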