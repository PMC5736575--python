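"""Wiring of the five sensory areas and synchronous state advancement.

Connectivity (all excitatory, Gaussian; lateral kernels Mexican-hat):

    R   <- external visual input + lateral
    V1  <- lateral + W^{V1,R} R + W^{V1,E} E + W^{V1,SC} SC + W^{V1,A} A
    E   <- lateral + W^{E,V1} V1 + W^{E,SC} SC
    A   <- external auditory input + lateral + W^{A,SC} SC + W^{A,V1} V1
    SC  <- lateral + W^{SC,R} R + W^{SC,V1} V1 + W^{SC,E} E + W^{SC,A} A

All areas advance synchronously (each step reads the previous step's
activities), so update order has no effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_dynamics import euler_step
from .params import AREAS, N, SOURCES, ModelParams, DEFAULT, SimClock
from .stimulation import StimulusSpec, TrialNoise, external_input
from .topology import SynapseSet

__all__ = ["NetworkState", "net_inputs", "area_net_input", "step_network"]


def net_inputs(
    y: dict[str, np.ndarray],
    synapses: SynapseSet,
    ext_r: np.ndarray,
    ext_a: np.ndarray,
) -> dict[str, np.ndarray]:
    """Net input vectors for all five areas from the current activities.

    Activity arrays may be (181,) or batched (B, 181); external inputs must
    broadcast accordingly.
    """
    u = {"R": ext_r + y["R"] @ synapses.lateral["R"]}
    for h in ("V1", "E", "A", "SC"):
        acc = y[h] @ synapses.lateral[h]
        for q in SOURCES[h]:
            acc = acc + y[q] @ synapses.inter[(h, q)].T
        if h == "A":
            acc = acc + ext_a
        u[h] = acc
    return u


def area_net_input(
    area: str,
    state: "NetworkState",
    ext_r: np.ndarray | None = None,
    ext_a: np.ndarray | None = None,
) -> np.ndarray:
    """Net input to one named area (see module docstring for the wiring)."""
    if area not in AREAS:
        raise KeyError(f"unknown area {area!r}")
    zero = np.zeros(N)
    u = net_inputs(
        state.y,
        state.synapses,
        zero if ext_r is None else ext_r,
        zero if ext_a is None else ext_a,
    )
    return u[area]


@dataclass
class NetworkState:
    """Full sensory-module state for a single trial."""

    synapses: SynapseSet
    y: dict[str, np.ndarray] = field(
        default_factory=lambda: {a: np.zeros(N) for a in AREAS}
    )
    y_sg: float = 0.0
    gaze: float = 0.0
    clock: SimClock = field(default_factory=SimClock)

    @classmethod
    def initial(cls, synapses: SynapseSet | None = None, dt: float = 0.1) -> "NetworkState":
        return cls(
            synapses=synapses if synapses is not None else SynapseSet.basal(),
            clock=SimClock(dt=dt),
        )


def step_network(
    state: NetworkState,
    stim: StimulusSpec | None,
    noise: TrialNoise | None = None,
    lesion_mask: np.ndarray | None = None,
    params: ModelParams = DEFAULT,
) -> NetworkState:
    """Advance the five sensory areas by one Euler step (synchronous update).

    External inputs are evaluated at the current gaze and time. A lesion
    mask (1 = intact, 0 = silenced V1 neuron) clamps both the net input and
    the activity of silenced V1 neurons to zero. The SG unit is not advanced
    here (see the oculomotor module / trial engine).
    """
    dt, t = state.clock.dt, state.clock.t
    if stim is not None:
        ext_r, ext_a = external_input(stim, state.gaze, t, noise, params.stimulus)
    else:
        ext_r = ext_a = np.zeros(N)
    u = net_inputs(state.y, state.synapses, ext_r, ext_a)
    if lesion_mask is not None:
        u["V1"] = u["V1"] * lesion_mask
    new_y = {a: euler_step(state.y[a], u[a], params.neuron, dt) for a in AREAS}
    if lesion_mask is not None:
        new_y["V1"] = new_y["V1"] * lesion_mask
    return NetworkState(
        synapses=state.synapses,
        y=new_y,
        y_sg=state.y_sg,
        gaze=state.gaze,
        clock=SimClock(dt=dt, t=t + dt),
    )
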