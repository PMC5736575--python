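# Model and methods

`colliculus` simulates audiovisual rehabilitation of hemianopia with a
firing-rate network of cortico-collicular loops coupled to a brainstem
saccade generator. This note documents the model, its parameters, the
numerical choices, and what the simulations do and do not establish.

## The sensory module

Five topologically organized areas — retina (R), primary visual cortex
(V1), extrastriate visual cortex (E), auditory area (A) and Superior
Colliculus (SC) — each contain N = 181 neurons with preferred *retinal*
positions −90°…+90° at 1° spacing (eye-centered coordinates; a stimulus at
head-centered azimuth p is seen by neuron i = p − g(t), where g is the
gaze). Every unit is a first-order sigmoidal element

    τ dy/dt = −y + F(u),      F(u) = 1 / (1 + exp(−(u − φ)ξ)),

with τ = 3 ms, φ = 12, ξ = 0.6, so activities live in (0, 1).

Connectivity:

* **Lateral (intra-area) kernels** — Mexican-hat difference of Gaussians of
  the inter-neuron distance d = |i − j| (linear distance, no wrap-around):
  amplitude 2/1.4 and widths 2°/24° (excitation/inhibition) in R, V1, E, A;
  the SC kernel is purely inhibitory (amplitude 3, width 24°). The
  self-connection (d = 0) is set to zero. Lateral kernels are fixed.
* **Inter-area synapses** — 12 excitatory Gaussian matrices
  W⁽ᴴ,Q⁾ᵢⱼ = W₀ exp(−(i−j)²/2σ²) wiring R→V1, R→SC, V1↔SC, V1↔E, E↔SC,
  A↔SC, A↔V1 with the basal central weights/widths of the reference
  parameterization (e.g. W₀ = 3.5, σ = 8° for the retino-collicular
  pathway). These are the plastic synapses.

Net inputs sum external input (R and A only), the lateral kernel, and the
inter-area drives; all areas advance synchronously by explicit forward
Euler at Δt = 0.1 ms (the update order is therefore irrelevant).

**External stimuli** are Gaussian profiles of the eye-centered distance to
the stimulus: visual amplitude V₀ = 20, σ = 2°; auditory A₀ = 17, σ = 32°
(audiovisual = both, spatially coincident by default). Gaussian noise with
std 10 % of the channel amplitude is superimposed. The noise vector is
drawn once per trial, indexed by offset from the stimulus center, and
*moves with the stimulus* during a saccade: it models stimulus-level
fluctuation, not receptor noise, and frozen-per-trial noise yields
trial-to-trial variability in SC activation (hence in saccade latency)
while keeping within-trial dynamics smooth. A `noise_mode="per_step"`
switch redraws the noise at every integration step for sensitivity checks.
Profiles are evaluated within ±3σ (truncating < 1.2 % of the amplitude)
and parts falling off the ±90° map are discarded.

## The oculomotor module

A single brainstem saccade-generator unit (SG) with the same sigmoid and
τ_SG = 70 ms pools the whole SC map through plastic weights (basal value
1.1 for all 181 synapses) and an empirical frontoparietal (FP) input: a
constant drive of amplitude 10 lasting as long as the stimulus, delayed by
δ ~ N(100, 10) ms drawn once per trial (clipped at ±3σ). In Fixed-Eyes
condition every SG input is gated off and the unit is clamped silent; in
patient trials with 100 ms stimuli the FP pathway is disabled altogether
(its delay makes it inoperative within the stimulus, and this matches the
absence of frontoparietal contributions assumed for those tasks).

A saccade starts the first time y_SG crosses the threshold 0.65. The
target θ_g is read once, at onset, from the maximally active SC neuron
(winner-takes-all; exact ties break toward the smaller |position| — a
measure-zero event under noise). The gaze then moves at a constant
0.4°/ms until it lands on θ_g and holds there; no second saccade occurs
within a trial. With τ_SG = 70 ms and threshold 0.65, a unit driven from
rest cannot cross before 70·ln(1/0.35) ≈ 73.5 ms plus the SC rise time,
which places the hard floor on simulated latencies near 75–80 ms; the
engine asserts ≥ 75 ms on every saccade it generates.

## Patients and conscious detection

A simulated hemianopic patient silences a subset (≥ ~85 %) of the 90 V1
neurons with preferred positions +1°…+90°; silenced neurons are clamped to
zero activity and zero net input and can never learn. The package ships
the 20 reference patients as a text fixture (`colliculus fixtures`), and
`make_patient` draws random ones. A *spared cluster* at position p is ≥ 2
surviving V1 neurons within p ± 4°.

A visual stimulus is *consciously detected* iff at some instant during its
presentation at least one V1 neuron **and** one E neuron simultaneously
exceed the detection threshold 0.2. The detection window closes at
stimulus offset (the stimulus must still be on the retina to drive V1/E).
Detections with a prior saccade onset are classified saccade-mediated
(compensatory), otherwise restitution-mediated.

## Plasticity

Sensory inter-area synapses potentiate with pre- and post-synaptic
thresholds and weight-dependent saturation,

    ΔW⁽ᴴ,Q⁾ᵢⱼ = γ₀ (Wmax − Wᵢⱼ) [yᵢᴴ − θ_post]⁺ [yⱼQ − θ_pre]⁺,

with γ₀ = 8·10⁻⁴ per 0.1 ms step, Wmax = 1.8·W₀ per connection, and
thresholds 0.2 everywhere except area A (0.7, modelling reduced attention
to the accessory auditory stimulus). After every increment the total
inter-area weight entering each neuron of A, V1, E, SC is rescaled to its
basal value (the retina receives no inter-area input), so potentiation is
competitive: trained synapses grow at the expense of the other afferents
of the same neuron. Because the rescale factor is ≤ 1 and the increment is
proportional to (Wmax − W), weights provably stay in [0, Wmax] without any
clipping, and the per-neuron sums are conserved to floating-point accuracy.

SC→SG weights follow ΔWⱼ = γ₀ (Wmax^SG − Wⱼ) · y_SG · [yⱼ^SC − 0.2]⁺ with
Wmax^SG = 3.6·1.1 and no normalization. The bare y_SG factor (no
post-synaptic threshold) is deliberate and load-bearing: early in
audiovisual training the SG unit is only weakly driven (y_SG ≈ 0.03–0.1),
and it is precisely the slow potentiation proportional to that small
activity that strengthens the SC→SG route until collicular drive alone
triggers saccades — the compensatory bootstrap. A post-threshold of 0.2
would freeze the pathway forever. The same bare factor lets visual-only
training (where y_SG ≤ ~0.006) deposit a slight, behaviorally inert drift
(< ~0.2) on W^SG at trained positions; the fixed-eyes paradigm clamps the
unit to zero and leaves the weights exactly basal.

Learning runs at every integration step from the settling time
T_off = 65 ms to the end of the trial.

## Protocols

Training sessions present 300 stimuli (75 each at 8°, 24°, 40°, 56°, in a
random permutation of the multiset) for 100 ms each, FP off, with synapses
carried across trials: paradigm A (audiovisual, eye movements), B
(audiovisual, fixed eyes), C (visual-only, eye movements). If the stimulus
is detected, the trial stops 10 ms after the first detected instant within
[T_off, 100 ms] (never beyond 100 ms), mimicking the button press of the
in-vivo protocols; starting the interruption clock at T_off keeps early
restitutive detections from cancelling learning at those positions.
Activities and gaze reset between trials.

Visual tests (learning off, FP off, visual-only 100 ms stimuli) probe the
trained positions (Test 1: 4 positions × 8 trials) or the whole blind
field (Test 2: 4°…60° step 2° × 2 trials), in both eye conditions.
Triggered-saccade counts and latencies exclude trials whose detection was
restitution-mediated.

## Numerical and performance choices

* Explicit Euler at Δt = 0.1 ms; halving Δt changes trajectories at O(Δt)
  (verified by a convergence test). Activities are clipped to [0, 1] as an
  inert safeguard.
* Batched trials (calibration, test sessions) integrate many trials as
  matrix products over a shared weight set in double precision; trials
  that already produced their saccade can be dropped from the batch.
* Training trials use a fused single-trial path: the 17 connection blocks
  are stacked and applied through a compiled kernel in single precision,
  with the per-neuron normalization factored out as a scaling vector so
  the rescale costs O(N) per step. All weight arithmetic (increments,
  normalization, the stored SynapseSet) stays in double precision; the
  two paths agree to ~1e-5 and an equivalence test enforces it. Weight
  entries below 1e-30 (far Gaussian tails) are flushed to zero in the
  single-precision kernels — denormal arithmetic is orders of magnitude
  slower and the dropped contributions are physically meaningless.
* Problem sizes: the packaged study runs 500-trial calibrations, a
  20-patient pre-training saccade survey (5 trials per position), and
  full 300-trial training sessions; the scripted acceptance run trains
  the five scattered-lesion reference patients. Full 20-patient training
  cohorts are available through the CLI (`colliculus train`).

## What the simulations show — and what they do not

The generator reproduces the *study conditions* of the modelled
experiments: stationary Gaussian stimuli on a 1-D azimuth, frozen
per-trial stimulus noise, all-or-none conscious detection, a single
saccade per trial with imposed constant velocity. Passing tests establish
that the implementation realizes the stated dynamics, plasticity and
protocols — not that the model captures real patients: there is no
elevation dimension, no head movement, no pre-saccadic receptive-field
remapping, no endogenous attention, and saccade kinematics are imposed
rather than emergent. Known quantitative limits: the exact inter-area
summation of the original formulation is only partially documented, and
our reconstruction, while qualitatively faithful (cortical saturation,
SC middle-level visual response, strong audiovisual enhancement,
express-saccade band after training), yields an intact-network visual
saccade latency distribution centered ~15 % above and an audiovisual one
~10 % below the reference values, with matching dispersions. The latency
floor, the training bootstrap, the paradigm contrasts and the patient
statistics are insensitive to this offset.

## Decoding conventions

* Winner-takes-all ties break toward the fovea (deterministic).
* Detection requires both V1 and E above 0.2 at the *same* instant — the
  strictest reading of joint suprathreshold activity.
* A saccade is counted "triggered" if its onset falls within the stimulus
  (onset ≤ 100 ms in tests).
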