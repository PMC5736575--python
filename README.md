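# colliculus

A firing-rate simulator of the cortico-collicular audiovisual network
behind multisensory rehabilitation of **hemianopia** — the loss of
conscious vision in one hemifield after unilateral V1 damage. The package
is for computational neuroscientists who want to reproduce, probe or
extend the model's account of why *audiovisual* training (a sound paired
with the unseen visual target) restores visual detection in the blind
field, while visual-only training barely does.

## The model in brief

Five retinotopic areas of 181 sigmoidal rate units each — retina **R**,
striate cortex **V1**, extrastriate cortex **E**, auditory area **A**, and
the multisensory Superior Colliculus **SC** — are wired by fixed
Mexican-hat lateral kernels and twelve plastic Gaussian inter-area
projections (R→V1, R→SC, V1↔SC, V1↔E, E↔SC, A↔SC, A↔V1). Each unit obeys

&nbsp;&nbsp;&nbsp;&nbsp;τ ẏ = −y + F(u), &nbsp; F(u) = 1/(1 + e^{−(u−φ)ξ}),

integrated by forward Euler at Δt = 0.1 ms. A brainstem saccade generator
(SG) pools the SC map (plus a delayed frontoparietal input in the intact
network) and triggers a saccade when its activity crosses 0.65; the target
is decoded winner-takes-all from the SC and the gaze moves at 0.4°/ms,
sliding the eye-centered stimulus representation across every map.
Hemianopic patients silence ≥85 % of the V1 neurons coding +1°…+90°; a
stimulus is consciously detected only when V1 *and* E simultaneously
exceed 0.2. During training, inter-area synapses potentiate by a
thresholded Hebbian rule with saturation and per-neuron normalization of
total incoming weight; the SC→SG weights potentiate in proportion to SG
activity itself, which is what lets audiovisual stimulation slowly
bootstrap an express-saccade (75–100 ms) compensatory route. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from colliculus import (
    SynapseSet, StimulusSpec, ModelParams, StimulusParams,
    load_reference_patients, simulate_trials, srt_statistics,
)

syn = SynapseSet.basal()

# intact network: saccade reaction times, frontoparietal pathway enabled
for modality in ("visual", "audiovisual"):
    specs = [StimulusSpec(modality=modality, p=24.0, duration=400.0)] * 100
    res = simulate_trials(syn, specs, rng=np.random.default_rng(42),
                          fp_enabled=True, stop_when_all_saccaded=True)
    s = srt_statistics(res.latencies)
    print(f"intact {modality:11s}: SRT = {s.mean:.0f} +/- {s.std:.0f} ms  (n={s.n})")

# an untrained hemianopic patient: the accessory sound rescues detection
# at a spared V1 cluster (noise disabled for a deterministic exemplar)
patient9 = load_reference_patients()[8]          # spares 8, 22, 27, 61, 76 deg
clean = ModelParams(stimulus=StimulusParams(noise_frac=0.0))
for modality in ("visual", "audiovisual"):
    res = simulate_trials(syn, [StimulusSpec(modality=modality, p=24.0, duration=100.0)],
                          rng=np.random.default_rng(0), lesion=patient9, params=clean)
    verdict = (f"detected at t = {res.t_detect[0]:.1f} ms ({res.mediated[0]})"
               if res.detected[0] else "not detected")
    print(f"patient 9, {modality:11s} stimulus at 24 deg: {verdict}")
```

prints

```
intact visual     : SRT = 237 +/- 32 ms  (n=96)
intact audiovisual: SRT = 134 +/- 9 ms  (n=100)
patient 9, visual      stimulus at 24 deg: not detected
patient 9, audiovisual stimulus at 24 deg: detected at t = 20.2 ms (restitution)
```

Audiovisual stimuli drive saccades ~100 ms earlier than visual ones
(multisensory enhancement in the SC), and in the blind field a
spatiotemporally coincident sound pushes extrastriate activity over the
awareness threshold where the visual stimulus alone stays invisible —
the "online" effect that the training protocols then consolidate.

Training and testing a patient:

```python
from colliculus import TrainingConfig, TestConfig
from colliculus.protocols import run_training_session, run_test_session

patient1 = load_reference_patients()[0]   # a single spared neuron at 43 deg
trained, log, _ = run_training_session(
    patient1, TrainingConfig(paradigm="A"), np.random.default_rng(7))
_, summary = run_test_session(
    patient1, trained, TestConfig(test=1, eye_condition="moving"),
    np.random.default_rng(1))
print(summary["saccade_pct"], summary["latencies"].min())
```

After the 300-trial audiovisual session the patient, who could not
saccade to any visual stimulus before, triggers express saccades
(latencies ≥ 75 ms, never above the 100 ms stimulus) on a majority of
Test-1 stimulations.

## Command line

```bash
colliculus calibrate --trials 500 --modality audiovisual --seed 1
colliculus train --paradigm A --patients reference:1,18,5,4,7 --seed 1 --out-dir runs/
colliculus posttrain-test --paradigm A --patients reference:1,18,5,4,7 \
    --weights-dir runs/ --out-dir runs/
colliculus report --pre runs/pre_cohort.csv --post runs/postA_cohort.csv
colliculus fixtures          # the 20 reference lesion patterns, as TSV
```

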