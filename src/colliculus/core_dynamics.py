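"""Single-neuron input-output relationship and explicit time integration.

Every unit in the network (the 181-neuron sensory areas and the single
brainstem saccade-generator unit) obeys the same first-order dynamics

    tau dy/dt = -y + F(u),    F(u) = 1 / (1 + exp(-(u - phi) * xi))

integrated with explicit forward Euler at dt = 0.1 ms by default.
"""

from __future__ import annotations

import numpy as np

from .params import NeuronParams

__all__ = ["sigmoid", "euler_step"]


def sigmoid(u, params: NeuronParams = NeuronParams()):
    """Sigmoidal activation F(u), strictly increasing, bounded in (0, 1).

    Parameters
    ----------
    u : array_like
        Net input (dimensionless input units).
    params : NeuronParams
        Supplies the center ``phi`` and slope ``xi``.
    """
    return 1.0 / (1.0 + np.exp(-(np.asarray(u, dtype=float) - params.phi) * params.xi))


def euler_step(y, u, params: NeuronParams = NeuronParams(), dt: float = 0.1):
    """One forward-Euler step of tau dy/dt = -y + F(u).

    Activities are clamped to [0, 1] afterwards as a numerical safeguard
    (inert except for round-off, since F is already in (0, 1)).

    Raises
    ------
    ValueError
        If ``dt > tau`` (the explicit step would be unstable).
    """
    if dt > params.tau:
        raise ValueError(f"dt={dt} exceeds tau={params.tau}: unstable Euler step")
    y = np.asarray(y, dtype=float)
    y_new = y + (dt / params.tau) * (-y + sigmoid(u, params))
    return np.clip(y_new, 0.0, 1.0)
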