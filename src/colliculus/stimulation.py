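"""External visual and auditory inputs in eye-centered coordinates.

A stimulus applied at head-centered azimuth ``p`` while the gaze is at ``g``
is centered on the neuron with preferred retinal position ``i = p - g``:
as the gaze shifts during a saccade, the input profile slides across the
retinotopic maps. Profiles are Gaussians (visual: V0 = 20, sigma = 2 deg;
auditory: A0 = 17, sigma = 32 deg) evaluated within +/-3 sigma, with
zero-mean Gaussian noise (std = 10% of the amplitude) sampled once per trial
and attached to the stimulus profile (it moves with the stimulus, modelling
stimulus-level fluctuation rather than receptor noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import N, POSITIONS, StimulusParams

__all__ = ["StimulusSpec", "TrialNoise", "sample_trial_noise", "external_input"]

MODALITIES = ("visual", "auditory", "audiovisual")


@dataclass(frozen=True)
class StimulusSpec:
    """One external stimulus: modality, head-centered position and timing."""

    modality: str
    p: float  # azimuth, head-centered deg
    duration: float = 100.0  # ms
    onset: float = 0.0  # ms
    p_auditory: float | None = None  # defaults to p (spatially coincident)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not -90 <= self.p <= 90:
            raise ValueError("stimulus position must lie in [-90, 90] deg")

    @property
    def has_visual(self) -> bool:
        return self.modality in ("visual", "audiovisual")

    @property
    def has_auditory(self) -> bool:
        return self.modality in ("auditory", "audiovisual")

    @property
    def pa(self) -> float:
        return self.p if self.p_auditory is None else self.p_auditory


@dataclass(frozen=True)
class TrialNoise:
    """Per-trial frozen noise, indexed by offset from the stimulus center.

    ``visual[k]`` / ``auditory[k]`` is the additive noise at offset
    k - 90 deg from the (possibly moving) stimulus center.
    """

    visual: np.ndarray  # (181,)
    auditory: np.ndarray  # (181,)


def sample_trial_noise(
    spec: StimulusSpec,
    rng: np.random.Generator,
    params: StimulusParams = StimulusParams(),
) -> TrialNoise:
    """Draw the trial's frozen noise vectors (std = noise_frac * amplitude).

    Both channels are always drawn (constant RNG consumption per trial);
    inactive channels are simply never applied.
    """
    nv = rng.normal(0.0, params.noise_frac * params.v0, N)
    na = rng.normal(0.0, params.noise_frac * params.a0, N)
    return TrialNoise(visual=nv, auditory=na)


def gaussian_profile(amp: float, sigma: float, center, truncate: float = 3.0) -> np.ndarray:
    """Gaussian input profile over the 181 positions, zero beyond +/-truncate*sigma.

    ``center`` may be a scalar (returns shape (181,)) or an array of trial
    centers (returns shape (B, 181)).
    """
    c = np.asarray(center, dtype=float)
    d = POSITIONS - c[..., None]
    prof = amp * np.exp(-(d**2) / (2.0 * sigma**2))
    prof[np.abs(d) > truncate * sigma] = 0.0
    return prof


def shifted_noise(noise_rel: np.ndarray, center) -> np.ndarray:
    """Noise vector re-indexed so it rides on the stimulus profile.

    The relative-offset vector is placed at integer offsets from the rounded
    stimulus center; offsets falling outside the array contribute zero.
    """
    c = np.asarray(center, dtype=float)
    idx = POSITIONS - np.rint(c[..., None]).astype(int) + 90  # offset index
    valid = (idx >= 0) & (idx < N)
    out = np.zeros(np.broadcast_shapes(c.shape + (N,), (N,)) if c.shape else (N,))
    out[valid] = noise_rel[idx[valid]]
    return out


def external_input(
    spec: StimulusSpec,
    gaze: float,
    t: float,
    noise: TrialNoise | None = None,
    params: StimulusParams = StimulusParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """External input vectors (ext_R, ext_A) at time ``t`` with gaze ``gaze``.

    Inputs are zero outside the stimulus window [onset, onset + duration];
    within it, the Gaussian profile (plus frozen noise, if given) is floored
    at zero. Visual drives the retina only; auditory drives area A only.
    """
    ext_r = np.zeros(N)
    ext_a = np.zeros(N)
    if not (spec.onset <= t <= spec.onset + spec.duration):
        return ext_r, ext_a
    if spec.has_visual:
        c = spec.p - gaze
        ext_r = gaussian_profile(params.v0, params.sigma_v, c)
        if noise is not None:
            ext_r = ext_r + shifted_noise(noise.visual, c)
        np.maximum(ext_r, 0.0, out=ext_r)
    if spec.has_auditory:
        c = spec.pa - gaze
        ext_a = gaussian_profile(params.a0, params.sigma_a, c)
        if noise is not None:
            ext_a = ext_a + shifted_noise(noise.auditory, c)
        np.maximum(ext_a, 0.0, out=ext_a)
    return ext_r, ext_a
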