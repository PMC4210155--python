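# Methods

This note documents the models implemented in `reflexgait`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Signal chain

### EMG conditioning

Raw EMG is band-pass filtered 20–500 Hz with a linear-phase windowed-sinc
FIR (Blackman window, order ≈ 4 × rate / 20 Hz, group delay compensated by
centred convolution), full-wave rectified, and low-pass filtered with a
4th-order Butterworth at 6 Hz applied forward–backward (zero lag;
effective 8th-order magnitude). Residual negative values are clipped at
zero. The Blackman window is used because the envelope must suppress DC
and electrode-offset leakage below 1e-3 of the input; a Hamming design of
the same order leaks ≈ 2e-3.

Two analytic checks pin the chain down: a DC input yields an envelope
below 1e-3, and a unit sinusoid inside the band yields the rectified mean
2/π ≈ 0.637 (note this holds for the *continuous* mean; at 10 samples per
cycle the discrete rectified mean is 0.6155, so the tests sample at ≥ 20
samples per cycle).

### Heel-strike detection

Rising crossings of `threshold_frac × channel max` (default 0.1), merged
within a 200 ms debounce window, then refined backwards along the
monotone loading flank to the onset sample. The refinement makes detection
onset-accurate (±1 sample on clean signals) rather than
threshold-dependent, and the fractional threshold makes it invariant to
positive rescaling of the channel.

### Strides, ERAs, heel template

A stride runs from one ipsilateral heel strike to the next. Event-related
averages use a symmetric ±1-stride lag window; events whose window leaves
the recording are dropped and counted. The mean heel-contact template
resamples each stride's heel segment to the mean stride length (linear
interpolation) before averaging, so the template is exactly one mean
stride long.

## System identification

The contact → envelope map is identified as an FIR filter of length two
mean strides with sample-by-sample LMS: estimate by convolution, error
against the conditioned envelope, coefficient update proportional to the
error-weighted input window. Defaults:

* **Learning rate** μ = 0.01, normalised per sample by the instantaneous
  window power. The normalisation floor is 1% of the *average* window
  energy rather than a machine epsilon: at record edges (zero padding) the
  instantaneous power vanishes and an unfloored normalised step diverges.
  The floor is proportional to input power, so scale covariance holds
  exactly (scaling the envelope by c scales the coefficients by c).
* **Iterations** 100 full passes over the record; on the shipped synthetic
  conditions the per-pass MSE is non-increasing and flat well before 100.
* **Initialization** h = 0.
* **Working rate** 50–100 Hz: the envelope is 6 Hz band-limited, so the
  pair is decimated (anti-aliased, zero-phase) before identification; this
  changes nothing physically and keeps 100 passes cheap.

**Identifiability.** Contact pulses are smooth and nearly periodic, so the
input excites only a low-dimensional subspace of the filter space, and the
6 Hz envelope filter bounds what any method can recover: bursts narrower
than τ ≈ 100 ms are visibly distorted by the conditioning itself (≈ 10%
NRMSE at τ = 80 ms). Three consequences are built in:

* the generator's default kernels use burst widths τ ≈ 120–130 ms —
  representable within the conditioning band and typical of gait
  activation envelopes (bursts spanning 15–30% of a stride);
* the batch least-squares oracle (`wiener_solution`) uses a truncated-SVD
  pseudo-inverse (relative cutoff 1e-2): directions the input does not
  excite are reported as zero — which is also what LMS from zero
  initialization leaves there — instead of being fitted to envelope
  ripple;
* identification quality is assessed on irregular walking (varying belt
  speed plus stride-timing jitter); on strictly periodic gait the lag-τ
  versus lag-(τ + one stride) ambiguity is unresolvable, which is exactly
  why the recordings use pseudo-random speed profiles.

Under high-SNR irregular-walking conditions (~220 strides), the LMS
coefficients agree with the batch solution to ≈ 2–3% NRMSE and with the
generator's ground-truth kernel to ≈ 8–10%.

**Truncation.** The identified two-stride response is cut to one stride
and the second half of the kept stride is multiplied by a decaying
half-Hanning window, so the tail reaches zero smoothly: this *selects* the
coefficients that generate a one-stride activation after heel contact.
The literal alternative (convolution with a half-Hanning kernel) smooths
rather than selects and is provided as `mode="convolve"` for comparison.

## Transfer-function building

The truncated response is convolved with the mean heel template, making an
impulse trigger equivalent to a typical FSR loading input. Landmarks
(alternating troughs/peaks) are located on a 25 ms moving-average-smoothed
copy with a 2% prominence floor; curve ends stand in as troughs when a
peak has no interior flank (flagged). Joint-action segments span trough
minimum to trough minimum. Rules where multiple peaks exist: the dominant
peak before 50% of the stride on the rectus femoris curve is hip flexion,
the dominant later peak is knee extension (re-triggered by the hip AEA and
started at its preceding trough); the biceps femoris and lateral
gastrocnemius knee-flexion segments are summed on the union of their
supports. Knee segments have the trigger-to-onset delay removed (the
walker's knee springs impose an equivalent latency); hip segments keep
theirs.

## Twitch model and curve fitting

Muscle twitches are modelled as the impulse response of a critically
damped second-order system. The implemented form is the bi-exponential
`e^{−t/τ2} − e^{−t/τ1}` normalised by its analytic peak, with the exact
critical limit `(t/τ)e^{1−t/τ}` as τ2 → τ1, so the fitted amplitude `A` is
always the curve's peak and the model is continuous across the limit
(relative difference < 1e-4 at τ2 = τ1(1 ± 1e-6)). The form is symmetric
under swapping τ1 ↔ τ2; fitted pairs are reported as found.

Fitting is bounded trust-region least squares (τ ∈ [5, 500] ms,
T0 ∈ [0, 500] ms, A > 0) from the neutral start τ1 = τ2 = 50 ms, T0 = 0,
A = segment peak. Because the exactly symmetric start is a saddle for
asymmetric optima, a small multistart set (asymmetric τ pair,
onset-matched T0) is tried and the lowest-cost solution returned. On
noiseless curves generated from all 48 published parameter rows the fit
recovers every constant to < 0.05%.

Finalization evaluates the fitted model at the 200 Hz control rate, clips
negatives, normalises the peak to 1 V, and fixes durations at 1000 ms
(hip, one stride) and 500 ms (knee, one step) with knee T0 forced to 0.
Curve characteristics: ΔT50 is the width between the first up-crossing and
last down-crossing of half the peak (linear interpolation between
samples); Tpeak is trigger-to-peak time.

**Stability heuristic.** A set is predicted stable when the hip-extensor
ΔT50 exceeds the hip-flexor ΔT50 (the stance hip needs a long enough
extension drive to carry the body over the swing leg). Applied to the
published characteristics table, the rule matches the observed outcome
for nine of twelve sets; 5A (stable despite rule-false) and 2B, 5B
(unstable despite rule-true) are shipped as documented exceptions — the
rule is a tendency, not a guarantee. Note also that ΔT50 computed from
the published fitted τ values does not reproduce the published ΔT50
table exactly (e.g. τ ≈ 86.9 ms implies ≈ 213 ms vs the printed 175 ms
for set 1B), so the characteristics table is carried as data in
`reflexgait.reference` rather than recomputed.

## Reflexive controller

Triggers are unit impulses on ground-contact rising edges and on upward
crossings of the hip anterior extreme angle (AEA). Wiring: hip flexion ←
contralateral contact; hip extension ← ipsilateral contact; knee flexion ←
contralateral contact; knee extension ← ipsilateral AEA. Drives are
convolutions of trigger trains with the finalized waveforms; overlapping
playbacks from repeated triggers are summed (the drive path is linear and
time-invariant by construction, asserted numerically). The extreme-angle
guard Γ ramps linearly from 1 to 0 over the final 5° before a threshold.
Output: V = per-motor gain × 2.3 (amplifier) × Γ·U, clipped at a ±4 V
rail. With all-zero sensors the output is identically zero — the
controller is purely reactive.

Controller thresholds and gains (AEA 12°, hip extremes ±32°, knee maximum
65°, unit motor gains) are artifact defaults tuned for the surrogate
plant below; they are not the hand-tuned values of any physical robot.

## Surrogate plant

The walker is a kinematic/first-order surrogate, deliberately not a
dynamics-faithful robot model. Per leg: the hip angle follows
`hip_deg_per_v × net voltage` through a first-order lag (τ = 120 ms,
2.5× slower on the loaded stance side), and with silent motors relaxes
monotonically toward neutral — the passive phase is first-order, with no
oscillation. The knee is a cascade of motor lag (50 ms) and spring
transmission lag (60 ms) with a hard stop at full extension (the
"kneecap") and a 70° flexion stop. Two effects make gait possible:

* **Passive pivot**: while the gait has momentum (a first-order gate on
  recent motor activity, τ = 250 ms), the body falls forward over the
  planted foot at 30°/s — the passive-dynamic walking phase analog.
  Without any motor activity there is no momentum and the walker stands
  still, so zero transfer functions produce zero motion.
* **Kinematic touchdown**: the swing foot lands when its geometric height
  (two equal 0.15 m segments) reaches the stance foot's ground plane while
  the swing hip leads by ≥ 5°. Landing with more than 20° of knee flexion
  is a scuffed touchdown (a stumble); real knee traces do show modest
  flexion at heel strike, hence the tolerance. Falls: hip height below
  0.82 × leg length, touchdown without protraction, or no step for 2.5 s.

With the shipped defaults and the published set 1B, the closed loop walks
indefinitely (26 strides in 20 s; stride 0.41 m / 0.76 s; 0.53 m/s =
1.78 leg lengths/s) and is bitwise deterministic for a fixed seed. The
per-set stable/unstable partition observed on the physical robot is *not*
reproduced by this surrogate (several published-stable sets scuff at
touchdown here because the plant's knee-extension timing, not its hip
timing, is the binding constraint); reproducing hardware outcomes per set
is out of scope.

## Synthetic data generator

The generator emulates the study conditions: a pseudo-random belt-speed
walk on a 0.05 m/s grid (each increment 0.05 or 0.1 m/s, direction
persistent with reflection at the range bounds, steered home at the end so
repeats never need an illegal jump); cadence model T(v) = 1.4 m / v
clipped to [0.8, 1.6] s with 2% stride-timing jitter (4% in identification
studies); contralateral strikes near mid-stride; heel FSR loading as an
asymmetric pulse (fast half-cosine attack over 15% of the loading window,
raised-cosine unloading) spanning 40% of the stride — the heel unloads
around heel-off, well before stance ends; EMG as unit-RMS 20–500 Hz
Gaussian carrier multiplied by (noise-free envelope + floor), pre-scaled
by √(π/2) so conditioning recovers the envelope with unit gain; a linear
speed gain on envelope amplitude (0.5 per m/s above the range minimum).
All randomness descends from one seed via fixed child streams.

What it does **not** emulate: EMG crosstalk and electrode artifacts,
treadmill belt dynamics, forefoot FSR biomechanics (those channels are
plausible filler; only the heels feed the pipeline), left/right
asymmetry, and within-stride gait-phase timing shifts with speed. Passing
tests therefore demonstrate the correctness and calibration of the
computational chain under its stated assumptions — linearity, speed acting
as a pure gain, envelope-band kernels — not performance on real
recordings.

## Numerical details worth knowing

* Envelope ripple after rectify-and-smooth of a 20–500 Hz carrier is
  ≈ 7–8% of the local envelope; it is the dominant noise term everywhere
  downstream (ERA convergence shows the expected 1/√N decay until this
  floor's residual systematics appear).
* The ERA noise oracle must include the generator's noise floor (the
  modulation is envelope + floor, not envelope alone).
* Fit tolerances: trust-region termination at 1e-14 (x, f, g); 50%
  crossings by linear interpolation; landmark ties resolve to the
  earliest sample.
* Degenerate inputs raise: empty heel template, flat transfer curve,
  all-zero fitted curve, fewer than two heel strikes, stride longer than
  the identified response.
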