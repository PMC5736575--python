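"""Trial engine: batch semantics, the fused training path, reproducibility."""

import numpy as np
import pytest

from colliculus.engine import simulate_trials
from colliculus.params import ModelParams, StimulusParams
from colliculus.plasticity import HebbianEngine
from colliculus.stimulation import StimulusSpec
from colliculus.topology import SynapseSet


def av(p=24.0, duration=100.0):
    return StimulusSpec(modality="audiovisual", p=p, duration=duration)


class TestBatchSemantics:
    def test_reproducible_given_seed(self, basal_synapses):
        specs = [StimulusSpec(modality="visual", p=24.0, duration=400.0)] * 5
        a = simulate_trials(basal_synapses, specs, rng=np.random.default_rng(9),
                            fp_enabled=True)
        b = simulate_trials(basal_synapses, specs, rng=np.random.default_rng(9),
                            fp_enabled=True)
        assert np.array_equal(a.t_s, b.t_s, equal_nan=True)
        assert np.array_equal(a.t_detect, b.t_detect, equal_nan=True)

    def test_fixed_eyes_produces_no_saccades(self, basal_synapses):
        specs = [StimulusSpec(modality="audiovisual", p=24.0, duration=400.0)] * 3
        res = simulate_trials(basal_synapses, specs, rng=np.random.default_rng(0),
                              fp_enabled=True, eye_condition="fixed",
                              record_every=50.0)
        assert not res.has_saccade.any()
        assert not res.traces["y_sg"].any()  # SG unit clamped silent
        assert not res.g_final.any()

    def test_learning_off_leaves_synapses_bit_identical(self, basal_synapses, patients):
        syn = basal_synapses.copy()
        before = {c: w.copy() for c, w in syn.inter.items()}
        w_sg_before = syn.w_sg.copy()
        simulate_trials(syn, [av()], rng=np.random.default_rng(1),
                        lesion=patients[9])
        for c in before:
            assert np.array_equal(syn.inter[c], before[c])
        assert np.array_equal(syn.w_sg, w_sg_before)

    def test_compaction_does_not_change_latencies(self, basal_synapses):
        """Dropping finished trials from the batch is purely an optimization."""
        specs = [StimulusSpec(modality="audiovisual", p=24.0, duration=400.0)] * 8
        full = simulate_trials(basal_synapses, specs, rng=np.random.default_rng(4),
                               fp_enabled=True)
        fast = simulate_trials(basal_synapses, specs, rng=np.random.default_rng(4),
                               fp_enabled=True, stop_when_all_saccaded=True)
        assert np.array_equal(full.t_s, fast.t_s, equal_nan=True)
        assert np.array_equal(full.theta, fast.theta, equal_nan=True)

    def test_mixed_durations_rejected(self, basal_synapses):
        specs = [av(duration=100.0), av(duration=200.0)]
        with pytest.raises(ValueError):
            simulate_trials(basal_synapses, specs, rng=np.random.default_rng(0))

    def test_per_step_noise_mode(self, basal_synapses):
        params = ModelParams(stimulus=StimulusParams(noise_mode="per_step"))
        spec = StimulusSpec(modality="visual", p=24.0, duration=20.0)
        res = simulate_trials(basal_synapses, [spec], rng=np.random.default_rng(2),
                              record_every=1.0, params=params)
        frozen = simulate_trials(basal_synapses, [spec], rng=np.random.default_rng(2),
                                 record_every=1.0)
        assert not np.allclose(res.traces["max"]["R"], frozen.traces["max"]["R"])


class TestFusedTrainingPath:
    def test_fused_matches_reference_implementation(self, basal_synapses, patients):
        """The optimized training path and the plain double-precision path
        produce the same trained weights (to single-precision tolerance)."""
        results = {}
        for fused in (True, False):
            syn = basal_synapses.copy()
            hebb = HebbianEngine(syn)
            rng = np.random.default_rng(3)
            for _ in range(3):
                simulate_trials(syn, [av(p=40.0)], rng=rng, lesion=patients[9],
                                learning=hebb, interrupt_on_detection=True,
                                _fused=fused)
            results[fused] = syn
        for c in results[True].inter:
            assert np.allclose(results[True].inter[c], results[False].inter[c],
                               atol=1e-4)
        assert np.allclose(results[True].w_sg, results[False].w_sg, atol=1e-5)

    def test_learning_requires_single_trial(self, basal_synapses):
        hebb = HebbianEngine(basal_synapses.copy())
        with pytest.raises(ValueError):
            simulate_trials(basal_synapses, [av(), av()],
                            rng=np.random.default_rng(0), learning=hebb)

    def test_interruption_rule_timing(self, basal_synapses, patients):
        """A trial detected early is stopped 10 ms after the settling time;
        learning stays confined to that short window."""
        syn = basal_synapses.copy()
        hebb = HebbianEngine(syn)
        # patient 9 at the 2-neuron cluster: audiovisual detection is fast
        res = simulate_trials(syn, [av(p=24.0)], rng=np.random.default_rng(5),
                              lesion=patients[9], learning=hebb,
                              interrupt_on_detection=True)
        assert res.detected[0]
        t_btn = max(res.t_detect[0], 65.0)
        assert res.t_end[0] == pytest.approx(min(t_btn + 10.0, 100.0), abs=0.11)

    def test_no_interruption_without_detection(self, basal_synapses, patients):
        syn = basal_synapses.copy()
        hebb = HebbianEngine(syn)
        res = simulate_trials(syn, [av(p=40.0)], rng=np.random.default_rng(5),
                              lesion=patients[9], learning=hebb,
                              interrupt_on_detection=True)
        assert not res.detected[0]
        assert res.t_end[0] == 100.0


class TestLesionHandling:
    def test_silenced_v1_strictly_zero_throughout(self, basal_synapses, patients):
        res = simulate_trials(basal_synapses, [av(p=40.0)],
                              rng=np.random.default_rng(0), lesion=patients[1],
                              record_every=5.0, record_full=True)
        y_v1 = res.traces["y"]["V1"][:, 0, :]  # (time, neurons)
        silenced = [i for i, m in enumerate(patients[1].v1_mask()) if m == 0]
        assert not y_v1[:, silenced].any()

    def test_detection_monotone_in_sc_feedback(self, basal_synapses, patients):
        """Zeroing the SC->E feedback can only remove detections."""
        spec = av(p=24.0)
        with_fb = simulate_trials(basal_synapses, [spec],
                                  rng=np.random.default_rng(8), lesion=patients[9])
        no_fb = basal_synapses.copy()
        no_fb.inter[("E", "SC")][:] = 0.0
        without = simulate_trials(no_fb, [spec], rng=np.random.default_rng(8),
                                  lesion=patients[9])
        assert with_fb.detected[0]
        assert not without.detected[0]

    def test_online_detection_matches_trace_decoder(self, basal_synapses, patients):
        """The engine's online detection agrees with the independent
        trace-based decoder applied to per-step V1/E maxima."""
        from colliculus.lesion import decode_detection

        spec = av(p=24.0)
        res = simulate_trials(basal_synapses, [spec], rng=np.random.default_rng(8),
                              lesion=patients[9], record_every=0.1)
        dec = decode_detection(
            res.traces["t"], res.traces["max"]["V1"][0], res.traces["max"]["E"][0],
            stim_duration=spec.duration,
            t_s=None if np.isnan(res.t_s[0]) else float(res.t_s[0]),
        )
        assert dec.detected == bool(res.detected[0])
        assert dec.t_detect == pytest.approx(res.t_detect[0], abs=0.11)
        assert dec.mediated_by == res.mediated[0]

    def test_per_trial_lesion_list(self, basal_synapses, patients):
        specs = [av(p=24.0)] * 2
        res = simulate_trials(basal_synapses, specs, rng=np.random.default_rng(8),
                              lesion=[patients[9], patients[1]])
        # same stimulus: the patient with the spared cluster detects, the
        # near-complete lesion does not
        assert res.detected[0]
        assert not res.detected[1]
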