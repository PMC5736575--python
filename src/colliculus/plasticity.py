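"""Hebbian potentiation with thresholds, saturation, and normalization.

Sensory inter-area synapses follow a thresholded potentiation rule

    dW_ij = gamma0 (Wmax - W_ij) [y_i^H - th_post]+ [y_j^Q - th_pre]+

applied every integration step once the settling time (65 ms) has elapsed,
followed by a per-postsynaptic-neuron normalization: the total inter-area
weight entering each neuron of areas A, V1, E, SC is rescaled back to its
basal (pre-training) value, so potentiated synapses grow at the expense of
the other synapses converging on the same neuron.

SC->SG weights follow a potentiation rule gated on the presynaptic side
only (dW proportional to y_SG itself, with the SC neuron above the 0.2
learning threshold), saturate at 3.6x basal, and are not normalized.
Lateral kernels never learn.
"""

from __future__ import annotations

import numpy as np

from .params import INTER_AREA, SOURCES, LearningParams, W0_SG_SC
from .topology import SynapseSet

__all__ = ["hebb_delta_sensory", "hebb_update_sg", "normalize_incoming", "HebbianEngine"]


def hebb_delta_sensory(w, y_post, y_pre, wmax, params: LearningParams, th_post, th_pre):
    """Potentiation increment (scalar or array), always >= 0 and saturating."""
    return (
        params.gamma0
        * (wmax - np.asarray(w, dtype=float))
        * np.maximum(np.asarray(y_post, dtype=float) - th_post, 0.0)
        * np.maximum(np.asarray(y_pre, dtype=float) - th_pre, 0.0)
    )


def hebb_update_sg(w_sg, y_sg, y_sc, params: LearningParams = LearningParams()):
    """Updated SC->SG weights: potentiation with a presynaptic gate only.

    dW_j = gamma0 (Wmax - W_j) y_SG [y_j^SC - 0.2]+ ; no normalization, and
    weights approach 3.6 * 1.1 = 3.96 asymptotically. The bare y_SG factor
    (no postsynaptic threshold) is what lets a weakly driven SG unit slowly
    strengthen its SC input until saccades bootstrap during audiovisual
    training, while leaving the pathway essentially untouched when SG
    activity stays near zero (visual-only training) and exactly basal when
    the unit is silenced (fixed-eyes training).
    """
    wmax = params.wmax_sg_factor * W0_SG_SC
    delta = (
        params.gamma0
        * (wmax - np.asarray(w_sg, dtype=float))
        * float(y_sg)
        * np.maximum(np.asarray(y_sc, dtype=float) - params.y_th, 0.0)
    )
    return w_sg + delta


def normalize_incoming(
    synapses: SynapseSet, area: str, basal_sums: np.ndarray
) -> None:
    """Rescale every incoming inter-area row of ``area`` to its basal sum (in place)."""
    if area == "R":
        raise ValueError("the retina receives no inter-area synapses")
    current = synapses.incoming_sums(area)
    factor = basal_sums / current
    for src in SOURCES[area]:
        synapses.inter[(area, src)] *= factor[:, None]


class HebbianEngine:
    """Efficient per-step learning on a SynapseSet during a training session.

    Precomputes saturation values and the per-neuron basal incoming sums
    (the normalization targets) once; ``step`` applies one increment +
    normalization cycle given the current activities. Normalization is exact:
    only rows that received an increment are rescaled (untouched rows already
    sit at their basal sum, an invariant of the rule).
    """

    def __init__(self, synapses: SynapseSet, params: LearningParams = LearningParams()):
        self.params = params
        self.wmax = {conn: params.wmax_factor * w0 for conn, (w0, _) in INTER_AREA.items()}
        self.wmax_sg = params.wmax_sg_factor * W0_SG_SC
        self.basal_sums = {h: synapses.incoming_sums(h) for h in SOURCES}

    def step(self, synapses: SynapseSet, y: dict[str, np.ndarray], y_sg: float) -> None:
        p = self.params
        for h in SOURCES:
            th_post = p.threshold(h)
            yh = y[h]
            pidx = np.flatnonzero(yh > th_post)
            if pidx.size == 0:
                continue
            post = yh[pidx] - th_post
            row_add = None
            for q in SOURCES[h]:
                yq = y[q]
                th_pre = p.threshold(q)
                qidx = np.flatnonzero(yq > th_pre)
                if qidx.size == 0:
                    continue
                w = synapses.inter[(h, q)]
                block = np.ix_(pidx, qidx)
                sub = w[block]
                delta = p.gamma0 * (self.wmax[(h, q)] - sub) * np.outer(
                    post, yq[qidx] - th_pre
                )
                w[block] = sub + delta
                add = delta.sum(axis=1)
                row_add = add if row_add is None else row_add + add
            if row_add is None:
                continue
            base = self.basal_sums[h][pidx]
            factor = base / (base + row_add)
            for q in SOURCES[h]:
                synapses.inter[(h, q)][pidx] *= factor[:, None]
        # SC -> SG pathway: presynaptic gate only, saturating, unnormalized
        if y_sg > 0.0:
            synapses.w_sg[:] = hebb_update_sg(synapses.w_sg, y_sg, y["SC"], p)
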