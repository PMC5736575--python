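"""Brainstem saccade generator: input pooling, initiation, decoding, kinematics.

The SG unit pools the SC population through the (plastic) SC->SG weights and
an empirical frontoparietal (FP) drive -- a constant input of amplitude 10
lasting as long as the stimulus but delayed by delta ~ N(100, 10) ms drawn
once per trial. A saccade starts the first time SG activity reaches the
saccade threshold (0.65); the target is the preferred position of the
maximally active SC neuron at onset (winner-takes-all, read once), and the
gaze then moves at a constant 0.4 deg/ms until it lands on the target.
In Fixed-Eyes condition (alpha_fix = 1) all SG inputs are gated off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import POSITIONS, OculomotorParams

__all__ = [
    "SaccadeEvent",
    "sample_fp_delay",
    "sg_input",
    "check_saccade_onset",
    "decode_target",
    "update_gaze",
]

#: minimum plausible saccade latency (ms); enforced on every simulated run
MIN_LATENCY = 75.0

# column order with smallest |position| first: argmax over this ordering
# implements the deterministic tie-break toward the fovea
_WTA_ORDER = np.lexsort((POSITIONS, np.abs(POSITIONS)))
_WTA_POS = POSITIONS[_WTA_ORDER]


@dataclass(frozen=True)
class SaccadeEvent:
    """Saccade onset time (= latency, stimulus onset at t = 0) and target."""

    t_s: float  # ms
    theta_g: float  # target gaze displacement, deg

    def __post_init__(self) -> None:
        if not -90 <= self.theta_g <= 90:
            raise ValueError("saccade target outside [-90, 90] deg")
        if self.t_s < 0:
            raise ValueError("saccade onset must be >= 0")


def sample_fp_delay(rng: np.random.Generator, params: OculomotorParams, size=None):
    """Per-trial FP delay, N(100, 10) ms truncated at +/-3 sigma."""
    d = rng.normal(params.fp_delay_mean, params.fp_delay_std, size)
    lo = params.fp_delay_mean - 3 * params.fp_delay_std
    hi = params.fp_delay_mean + 3 * params.fp_delay_std
    return np.clip(d, lo, hi)


def sg_input(
    y_sc: np.ndarray,
    w_sg: np.ndarray,
    t: float,
    stim_duration: float,
    fp_delay: float,
    alpha_fix: int = 0,
    fp_enabled: bool = True,
    params: OculomotorParams = OculomotorParams(),
) -> float:
    """Overall SG input u = SC term + FP term, gated by the fixation flag.

    The FP rectangular gate is active for 0 <= t - delta <= D; the whole FP
    pathway is dropped when ``fp_enabled`` is false (short-stimulus patient
    trials, where the delayed FP input would never become operative).
    """
    if alpha_fix:
        return 0.0
    u = float(y_sc @ w_sg)
    if fp_enabled and 0.0 <= t - fp_delay <= stim_duration:
        u += params.i0_fp
    return u


def decode_target(y_sc: np.ndarray) -> float:
    """Winner-takes-all readout of the SC map (ties -> smallest |position|)."""
    y_sc = np.asarray(y_sc)
    if not np.any(y_sc > 0):
        raise ValueError("cannot decode a saccade target from a silent SC")
    # first occurrence of the max in fovea-first ordering = tie-break
    return float(_WTA_POS[np.argmax(y_sc[..., _WTA_ORDER], axis=-1)])


def check_saccade_onset(
    y_sg: float,
    y_sc: np.ndarray,
    t: float,
    params: OculomotorParams = OculomotorParams(),
) -> SaccadeEvent | None:
    """First crossing of the saccade threshold triggers and decodes the saccade."""
    if y_sg >= params.y_th_sg:
        return SaccadeEvent(t_s=t, theta_g=decode_target(y_sc))
    return None


def update_gaze(
    g: float,
    event: SaccadeEvent | None,
    t: float,
    dt: float,
    params: OculomotorParams = OculomotorParams(),
) -> float:
    """Constant-velocity gaze drive toward the target, clamped on arrival.

    Without a saccade event (or before onset) the gaze stays where it is
    (0 deg throughout the trial in practice).
    """
    if event is None or t <= event.t_s or g == event.theta_g:
        return g
    step = np.sign(event.theta_g - g) * params.v_g * dt
    g_new = g + step
    if (event.theta_g - g_new) * (event.theta_g - g) <= 0:  # reached / crossed
        return event.theta_g
    return g_new
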