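"""Model parameters and network constants.

All defaults reproduce the basal (pre-training) parameterization of the
cortico-collicular audiovisual network: five sensory areas (retina R, striate
cortex V1, extrastriate cortex E, auditory area A, superior colliculus SC) of
181 neurons each, with preferred retinal positions -90..+90 deg at 1 deg
spacing, plus a single brainstem saccade-generator (SG) unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: number of neurons per area
N = 181

#: preferred retinal positions (deg), -90 .. +90 at 1 deg spacing
POSITIONS = np.arange(-90, 91)

#: sensory areas, in update order
AREAS = ("R", "V1", "E", "A", "SC")

#: inter-area Gaussian connections (target, source) -> (W0 central weight, sigma deg)
INTER_AREA: dict[tuple[str, str], tuple[float, float]] = {
    ("V1", "R"): (5.0, 4.0),
    ("SC", "R"): (3.5, 8.0),
    ("SC", "V1"): (0.5, 8.0),
    ("V1", "SC"): (0.4, 8.0),
    ("E", "V1"): (3.0, 6.0),
    ("V1", "E"): (1.0, 6.0),
    ("SC", "E"): (0.5, 8.0),
    ("E", "SC"): (0.75, 8.0),
    ("SC", "A"): (2.5, 16.0),
    ("A", "SC"): (0.25, 16.0),
    ("A", "V1"): (0.4, 8.0),
    ("V1", "A"): (0.4, 8.0),
}

#: source areas feeding each target area (retina receives no inter-area input)
SOURCES: dict[str, tuple[str, ...]] = {
    "V1": ("R", "E", "SC", "A"),
    "E": ("V1", "SC"),
    "SC": ("R", "V1", "E", "A"),
    "A": ("SC", "V1"),
}

#: basal weight of every SC -> SG synapse
W0_SG_SC = 1.1


@dataclass(frozen=True)
class NeuronParams:
    """First-order sigmoidal unit: tau dy/dt = -y + F(u)."""

    tau: float = 3.0  # membrane time constant, ms
    phi: float = 12.0  # sigmoid center, input units
    xi: float = 0.6  # sigmoid slope, 1/input units

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.xi <= 0:
            raise ValueError("xi must be > 0")


@dataclass(frozen=True)
class LateralKernelParams:
    """Mexican-hat (difference-of-Gaussians) intra-area kernel."""

    l_ex0: float = 2.0  # excitatory amplitude
    l_in0: float = 1.4  # inhibitory amplitude
    sigma_ex: float = 2.0  # deg
    sigma_in: float = 24.0  # deg

    def __post_init__(self) -> None:
        if self.l_ex0 < 0 or self.l_in0 < 0:
            raise ValueError("kernel amplitudes must be >= 0")
        if self.sigma_ex <= 0 or self.sigma_in <= 0:
            raise ValueError("kernel widths must be > 0")


#: lateral kernels per area; SC is purely inhibitory
LATERAL: dict[str, LateralKernelParams] = {
    "R": LateralKernelParams(),
    "V1": LateralKernelParams(),
    "E": LateralKernelParams(),
    "A": LateralKernelParams(),
    "SC": LateralKernelParams(l_ex0=0.0, l_in0=3.0, sigma_ex=2.0, sigma_in=24.0),
}


@dataclass(frozen=True)
class StimulusParams:
    """External-stimulus profile amplitudes/widths and noise level."""

    v0: float = 20.0  # visual amplitude
    sigma_v: float = 2.0  # visual spatial std, deg
    a0: float = 17.0  # auditory amplitude
    sigma_a: float = 32.0  # auditory spatial std, deg
    noise_frac: float = 0.10  # noise std as fraction of amplitude
    #: 'frozen': one spatial noise draw per trial, held for the whole trial
    #: (the default; keeps within-trial dynamics smooth while producing
    #: trial-to-trial variability); 'per_step': redrawn every integration step
    noise_mode: str = "frozen"

    def __post_init__(self) -> None:
        if self.noise_mode not in ("frozen", "per_step"):
            raise ValueError("noise_mode must be 'frozen' or 'per_step'")


@dataclass(frozen=True)
class OculomotorParams:
    """SG unit, frontoparietal input and gaze kinematics."""

    tau_sg: float = 70.0  # SG time constant, ms
    y_th_sg: float = 0.65  # saccade threshold on SG activity
    i0_fp: float = 10.0  # frontoparietal input amplitude
    fp_delay_mean: float = 100.0  # ms
    fp_delay_std: float = 10.0  # ms
    v_g: float = 0.4  # saccade velocity, deg/ms

    def __post_init__(self) -> None:
        if not 0 < self.y_th_sg < 1:
            raise ValueError("saccade threshold must lie in (0,1)")
        if self.v_g <= 0:
            raise ValueError("saccade velocity must be > 0")


@dataclass(frozen=True)
class LearningParams:
    """Hebbian potentiation with thresholds, saturation and normalization.

    ``wmax_factor`` scales every sensory inter-area matrix's saturation to
    1.8x its basal central weight; the SC->SG vector saturates at 3.6x basal.
    Learning thresholds are 0.2 everywhere except area A (0.7, mimicking
    reduced attention to the accessory auditory stimulus).
    """

    gamma0: float = 8e-4  # per-step base rate at dt = 0.1 ms
    wmax_factor: float = 1.8
    wmax_sg_factor: float = 3.6
    y_th: float = 0.2  # pre/post threshold, areas R, V1, E, SC, SG
    y_th_a: float = 0.7  # pre/post threshold, area A
    t_off: float = 65.0  # settling time before learning starts, ms

    def threshold(self, area: str) -> float:
        return self.y_th_a if area == "A" else self.y_th


@dataclass(frozen=True)
class SimClock:
    """Integration step and current time (ms)."""

    dt: float = 0.1
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all tunable parameter groups with basal defaults."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    sg_neuron: NeuronParams = field(default_factory=lambda: NeuronParams(tau=70.0))
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    oculomotor: OculomotorParams = field(default_factory=OculomotorParams)
    learning: LearningParams = field(default_factory=LearningParams)
    dt: float = 0.1  # ms
    y_th_detect: float = 0.2  # conscious-detection threshold in V1 and E


DEFAULT = ModelParams()
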