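"""Hebbian potentiation, saturation, and per-neuron weight normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from colliculus.params import AREAS, N, SOURCES, LearningParams
from colliculus.plasticity import (
    HebbianEngine,
    hebb_delta_sensory,
    hebb_update_sg,
    normalize_incoming,
)
from colliculus.topology import SynapseSet

LP = LearningParams()


class TestSensoryDelta:
    def test_reference_value(self):
        # basal retino-collicular weight, saturated activities:
        # 8e-4 * (6.3 - 3.5) * 0.8 * 0.8
        d = hebb_delta_sensory(3.5, 1.0, 1.0, wmax=6.3, params=LP, th_post=0.2, th_pre=0.2)
        assert d == pytest.approx(1.4336e-3)

    def test_subthreshold_gates(self):
        assert hebb_delta_sensory(3.5, 1.0, 0.1, 6.3, LP, 0.2, 0.2) == 0.0
        assert hebb_delta_sensory(3.5, 0.15, 1.0, 6.3, LP, 0.2, 0.2) == 0.0

    def test_saturation(self):
        assert hebb_delta_sensory(6.3, 1.0, 1.0, 6.3, LP, 0.2, 0.2) == 0.0

    @given(
        st.floats(0.0, 6.3),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
    )
    def test_nonnegative_and_bounded(self, w, y_post, y_pre):
        d = hebb_delta_sensory(w, y_post, y_pre, 6.3, LP, 0.2, 0.2)
        assert d >= 0.0
        assert w + d <= 6.3 + 1e-12


class TestSGRule:
    def test_silent_sg_freezes_weights(self):
        w = np.full(N, 1.1)
        out = hebb_update_sg(w, 0.0, np.ones(N), LP)
        assert np.array_equal(out, w)

    def test_saturated_weight_stops(self):
        w = np.full(N, 3.96)
        out = hebb_update_sg(w, 0.9, np.ones(N), LP)
        assert np.allclose(out, 3.96)

    def test_presynaptic_gate(self):
        w = np.full(N, 1.1)
        y_sc = np.full(N, 0.15)  # below the 0.2 learning threshold
        assert np.array_equal(hebb_update_sg(w, 0.9, y_sc, LP), w)

    def test_growth_scales_with_sg_activity(self):
        w = np.full(N, 1.1)
        y_sc = np.full(N, 1.0)
        d1 = hebb_update_sg(w, 0.1, y_sc, LP) - w
        d2 = hebb_update_sg(w, 0.2, y_sc, LP) - w
        assert np.allclose(d2, 2 * d1)


class TestNormalization:
    def test_retina_rejected(self, basal_synapses):
        with pytest.raises(ValueError):
            normalize_incoming(basal_synapses.copy(), "R", np.ones(N))

    def test_restores_basal_sums(self, basal_synapses):
        syn = basal_synapses.copy()
        target = basal_synapses.incoming_sums("SC")
        rng = np.random.default_rng(0)
        for src in SOURCES["SC"]:
            syn.inter[("SC", src)] += rng.uniform(0, 0.1, (N, N))
        normalize_incoming(syn, "SC", target)
        assert np.allclose(syn.incoming_sums("SC"), target, rtol=1e-12)


class TestHebbianEngine:
    def _active_state(self, peak_area="SC", pos=114):
        y = {a: np.zeros(N) for a in AREAS}
        prof = np.exp(-((np.arange(N) - pos) ** 2) / 18.0)
        y["R"] = 0.95 * prof
        y["SC"] = 0.8 * prof
        y["V1"] = 0.9 * prof
        y["E"] = 0.85 * prof
        y["A"] = 0.85 * prof
        return y

    def test_subthreshold_state_is_fixed_point(self, basal_synapses):
        syn = basal_synapses.copy()
        engine = HebbianEngine(syn)
        y = {a: np.full(N, 0.15) for a in AREAS}
        before = {c: w.copy() for c, w in syn.inter.items()}
        engine.step(syn, y, y_sg=0.15)
        for c in before:
            assert np.array_equal(syn.inter[c], before[c])

    def test_conservation_after_every_step(self, basal_synapses):
        """Per-neuron incoming sums stay at basal to 1e-9 relative."""
        syn = basal_synapses.copy()
        engine = HebbianEngine(syn)
        targets = {h: basal_synapses.incoming_sums(h) for h in SOURCES}
        y = self._active_state()
        for _ in range(200):
            engine.step(syn, y, y_sg=0.5)
            for h in SOURCES:
                assert np.allclose(syn.incoming_sums(h), targets[h], rtol=1e-9)

    def test_weights_bounded_and_potentiation_localized(self, basal_synapses):
        syn = basal_synapses.copy()
        engine = HebbianEngine(syn)
        wmax = syn.wmax()
        y = self._active_state()
        for _ in range(500):
            engine.step(syn, y, y_sg=0.5)
        for c, w in syn.inter.items():
            assert np.all(w >= 0.0)
            assert np.all(w <= wmax[c] + 1e-9)
        # the co-active synapse grew; a synapse onto the same neuron from a
        # silent region shrank (normalization redistributes)
        w_scr = syn.inter[("SC", "R")]
        basal = basal_synapses.inter[("SC", "R")]
        assert w_scr[114, 114] > basal[114, 114]
        assert w_scr[114, 100] < basal[114, 100]

    def test_auditory_threshold_is_higher(self, basal_synapses):
        """A-side activity at 0.6 (< 0.7) must not drive learning on A synapses."""
        syn = basal_synapses.copy()
        engine = HebbianEngine(syn)
        y = self._active_state()
        y["A"] = np.minimum(y["A"], 0.6)
        before_a = {c: syn.inter[c].copy() for c in (("SC", "A"), ("A", "SC"), ("A", "V1"))}
        engine.step(syn, y, y_sg=0.0)
        # A as postsynaptic area is fully gated: its incoming matrices get no
        # increment and hence no renormalization either
        assert np.array_equal(syn.inter[("A", "SC")], before_a[("A", "SC")])
        assert np.array_equal(syn.inter[("A", "V1")], before_a[("A", "V1")])
        # A as presynaptic area contributes no potentiation to SC; its weights
        # onto SC can only shrink (normalization against other sources' growth)
        assert np.all(syn.inter[("SC", "A")] <= before_a[("SC", "A")] + 1e-15)
        assert not np.array_equal(syn.inter[("SC", "A")], before_a[("SC", "A")])

    def test_silenced_neurons_never_learn(self, basal_synapses, patients):
        syn = basal_synapses.copy()
        engine = HebbianEngine(syn)
        mask = patients[9].v1_mask()
        y = self._active_state()
        y["V1"] *= mask
        before = syn.inter[("V1", "R")].copy()
        for _ in range(50):
            engine.step(syn, y, y_sg=0.0)
        silenced_rows = np.flatnonzero(mask == 0)
        assert np.array_equal(syn.inter[("V1", "R")][silenced_rows], before[silenced_rows])
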