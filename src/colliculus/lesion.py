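"""Hemianopic patients, spared-cluster queries, and detection decoding.

A simulated patient is a set of silenced V1 neurons in the +1..+90 deg
hemifield (the left hemifield V1 stays intact); silenced neurons are hard
clamped to zero activity and zero net input for the whole simulation. A
visual stimulus is consciously detected only if, at some instant during its
presentation, at least one neuron in V1 AND one in E simultaneously exceed
the detection threshold (0.2). Detections are classified saccade-mediated if
a saccade onset preceded the detection instant, else restitution-mediated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .params import N, POSITIONS

__all__ = [
    "Patient",
    "DetectionResult",
    "make_patient",
    "load_reference_patients",
    "spared_cluster",
    "decode_detection",
]

#: damaged hemifield positions (deg)
BLIND_FIELD = np.arange(1, 91)


@dataclass(frozen=True)
class Patient:
    """Lesion specification: spared V1 positions within +1..+90 deg."""

    id: int | str
    spared_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        sp = tuple(sorted(int(p) for p in self.spared_positions))
        object.__setattr__(self, "spared_positions", sp)
        if any(p < 1 or p > 90 for p in sp):
            raise ValueError("spared positions must lie in +1..+90 deg")
        if len(set(sp)) != len(sp):
            raise ValueError("duplicate spared positions")

    @property
    def silenced_positions(self) -> tuple[int, ...]:
        return tuple(p for p in BLIND_FIELD if p not in self.spared_positions)

    @property
    def n_silenced(self) -> int:
        return 90 - len(self.spared_positions)

    def v1_mask(self) -> np.ndarray:
        """Intactness mask over the 181 V1 neurons (1 intact, 0 silenced)."""
        mask = np.ones(N)
        silenced = set(self.silenced_positions)
        mask[[i for i, p in enumerate(POSITIONS) if p in silenced]] = 0.0
        return mask


@dataclass(frozen=True)
class DetectionResult:
    detected: bool
    t_detect: float | None = None  # ms
    mediated_by: str | None = None  # 'restitution' | 'saccade'

    def __post_init__(self) -> None:
        if self.detected and self.t_detect is None:
            raise ValueError("detected trials must carry a detection time")
        if self.mediated_by not in (None, "restitution", "saccade"):
            raise ValueError("mediated_by must be 'restitution' or 'saccade'")


def make_patient(
    rng: np.random.Generator,
    min_lesion_frac: float = 0.85,
    id: int | str = "random",
) -> Patient:
    """Random hemianopic patient: silence >= 85% of blind-hemifield V1 neurons.

    The lesion fraction is drawn uniformly in [min_lesion_frac, 1], and the
    silenced set sampled uniformly without replacement.
    """
    if not 0 <= min_lesion_frac <= 1:
        raise ValueError("min_lesion_frac must lie in [0, 1]")
    frac = rng.uniform(min_lesion_frac, 1.0)
    n_silence = int(np.ceil(frac * BLIND_FIELD.size))
    silenced = rng.choice(BLIND_FIELD, size=n_silence, replace=False)
    spared = tuple(int(p) for p in BLIND_FIELD if p not in set(silenced.tolist()))
    return Patient(id=id, spared_positions=spared)


def load_reference_patients() -> list[Patient]:
    """The 20 reference simulated patients, from the packaged fixture table.

    Each row is validated: silenced count + spared count must equal 90.
    """
    text = (
        resources.files("colliculus.data").joinpath("reference_patients.tsv").read_text()
    )
    patients = []
    for line in text.strip().splitlines()[1:]:
        pid, n_str, spared_str = line.split("\t")
        spared = tuple(int(tok.rstrip("°")) for tok in spared_str.split())
        n = int(n_str)
        if n + len(spared) != 90:
            raise ValueError(
                f"patient {pid}: silenced count {n} + {len(spared)} spared != 90"
            )
        patients.append(Patient(id=int(pid), spared_positions=spared))
    if len(patients) != 20:
        raise ValueError("expected 20 reference patients")
    return patients


def spared_cluster(patient: Patient, p: float) -> int:
    """Size of the spared-V1 cluster around position p (0 if fewer than 2).

    A cluster exists if >= 2 spared neurons lie within [p - 4, p + 4] deg;
    counts of 0 or 1 mean no cluster and are returned as 0.
    """
    count = sum(1 for q in patient.spared_positions if p - 4 <= q <= p + 4)
    return count if count >= 2 else 0


def decode_detection(
    times: np.ndarray,
    v1_max: np.ndarray,
    e_max: np.ndarray,
    stim_duration: float,
    t_s: float | None = None,
    threshold: float = 0.2,
) -> DetectionResult:
    """Decode conscious detection from per-instant V1/E maximum activities.

    Operates on recorded traces (one sample per instant): the stimulus is
    detected at the first instant t <= stimulus end where both areas exceed
    the threshold. ``t_s`` (saccade onset, if any) classifies the mediation.
    """
    window = times <= stim_duration + 1e-9
    hit = window & (v1_max > threshold) & (e_max > threshold)
    if not np.any(hit):
        return DetectionResult(detected=False)
    t_detect = float(times[np.argmax(hit)])
    mediated = "saccade" if (t_s is not None and t_s < t_detect) else "restitution"
    return DetectionResult(detected=True, t_detect=t_detect, mediated_by=mediated)
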