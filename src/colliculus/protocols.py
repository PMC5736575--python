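"""Experimental logic: single trials, training paradigms A/B/C, visual tests.

Training paradigms (300 trials, 75 per position at 8/24/40/56 deg, random
order, 100 ms stimuli, FP input excluded):

  A  audiovisual stimulation, eye movements allowed
  B  audiovisual stimulation, fixed eyes (SG silenced)
  C  visual-only stimulation, eye movements allowed

During training, a trial is interrupted 10 ms after conscious detection
(never beyond the 100 ms stimulus end), mimicking the subject's button
press; learning starts after the 65 ms settling time and synapses persist
across trials. Visual Test 1 (trained positions x 8 trials) and Visual
Test 2 (4..60 deg step 2 x 2 trials) probe detection with visual-only
100 ms stimuli, learning off, in both eye conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import BatchResult, FusedContext, simulate_trials
from .lesion import Patient
from .params import DEFAULT, ModelParams
from .plasticity import HebbianEngine
from .stimulation import StimulusSpec
from .topology import SynapseSet

__all__ = [
    "TrainingConfig",
    "TestConfig",
    "TrialRecord",
    "run_trial",
    "run_training_session",
    "run_test_session",
]

PARADIGMS = {
    "A": {"modality": "audiovisual", "eye_condition": "moving"},
    "B": {"modality": "audiovisual", "eye_condition": "fixed"},
    "C": {"modality": "visual", "eye_condition": "moving"},
}


@dataclass(frozen=True)
class TrainingConfig:
    paradigm: str = "A"
    positions: tuple[float, ...] = (8.0, 24.0, 40.0, 56.0)
    trials_per_position: int = 75
    stimulus_duration: float = 100.0  # ms
    snapshot_at: tuple[int, ...] = ()  # trial counts at which to snapshot synapses

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError("paradigm must be one of 'A', 'B', 'C'")

    @property
    def total_trials(self) -> int:
        return self.trials_per_position * len(self.positions)

    @property
    def modality(self) -> str:
        return PARADIGMS[self.paradigm]["modality"]

    @property
    def eye_condition(self) -> str:
        return PARADIGMS[self.paradigm]["eye_condition"]


@dataclass(frozen=True)
class TestConfig:
    test: int = 1  # 1: trained positions x 8; 2: 4..60 step 2 x 2
    eye_condition: str = "moving"
    stimulus_duration: float = 100.0

    def __post_init__(self) -> None:
        if self.test not in (1, 2):
            raise ValueError("test must be 1 or 2")
        if self.eye_condition not in ("moving", "fixed"):
            raise ValueError("eye_condition must be 'moving' or 'fixed'")

    @property
    def positions(self) -> tuple[float, ...]:
        if self.test == 1:
            return (8.0, 24.0, 40.0, 56.0)
        return tuple(float(p) for p in range(4, 61, 2))

    @property
    def repeats(self) -> int:
        return 8 if self.test == 1 else 2

    @property
    def n_trials(self) -> int:
        return len(self.positions) * self.repeats


@dataclass
class TrialRecord:
    """Outcome of one trial (metadata + saccade + detection)."""

    patient_id: int | str | None
    protocol: str
    position: float
    modality: str
    eye_condition: str
    duration: float
    t_s: float | None
    theta_g: float | None
    g_final: float
    detected: bool
    t_detect: float | None
    mediated_by: str | None
    t_end: float
    traces: dict | None = None


def _records_from_batch(
    result: BatchResult,
    specs: Sequence[StimulusSpec],
    *,
    patient_id,
    protocol: str,
    eye_condition: str,
) -> list[TrialRecord]:
    out = []
    for b, s in enumerate(specs):
        ts = result.t_s[b]
        td = result.t_detect[b]
        out.append(
            TrialRecord(
                patient_id=patient_id,
                protocol=protocol,
                position=s.p,
                modality=s.modality,
                eye_condition=eye_condition,
                duration=s.duration,
                t_s=None if np.isnan(ts) else float(ts),
                theta_g=None if np.isnan(ts) else float(result.theta[b]),
                g_final=float(result.g_final[b]),
                detected=bool(result.detected[b]),
                t_detect=None if np.isnan(td) else float(td),
                mediated_by=result.mediated[b] or None,
                t_end=float(result.t_end[b]),
                traces=result.traces,
            )
        )
    return out


def run_trial(
    synapses: SynapseSet,
    stim: StimulusSpec,
    *,
    rng: np.random.Generator,
    patient: Patient | None = None,
    eye_condition: str = "moving",
    fp_enabled: bool = False,
    learning: HebbianEngine | None = None,
    interrupt_on_detection: bool = False,
    record_every: float | None = None,
    record_full: bool = False,
    params: ModelParams = DEFAULT,
    protocol: str = "trial",
    _ctx=None,
) -> TrialRecord:
    """One trial from central fixation and quiescence; see the engine for semantics."""
    res = simulate_trials(
        synapses,
        [stim],
        rng=rng,
        lesion=patient,
        eye_condition=eye_condition,
        fp_enabled=fp_enabled,
        learning=learning,
        interrupt_on_detection=interrupt_on_detection,
        record_every=record_every,
        record_full=record_full,
        params=params,
        _ctx=_ctx,
    )
    return _records_from_batch(
        res,
        [stim],
        patient_id=None if patient is None else patient.id,
        protocol=protocol,
        eye_condition=eye_condition,
    )[0]


def run_training_session(
    patient: Patient,
    config: TrainingConfig,
    rng: np.random.Generator,
    *,
    synapses: SynapseSet | None = None,
    params: ModelParams = DEFAULT,
) -> tuple[SynapseSet, list[TrialRecord], dict[int, SynapseSet]]:
    """Run one full training session on a patient.

    Starts from the basal configuration (or a provided SynapseSet, which is
    not modified), presents the position sequence as a random permutation of
    the 300-trial multiset, and carries the synaptic state across trials.
    Returns the trained SynapseSet, the per-trial log, and any requested
    mid-session snapshots (keyed by completed-trial count).
    """
    syn = (synapses if synapses is not None else SynapseSet.basal()).copy()
    hebb = HebbianEngine(syn, params.learning)
    ctx = FusedContext(syn)  # carried across trials; synced at snapshots/end
    sequence = np.repeat(config.positions, config.trials_per_position)
    sequence = sequence[rng.permutation(sequence.size)]
    log: list[TrialRecord] = []
    snapshots: dict[int, SynapseSet] = {}
    for k, p in enumerate(sequence, start=1):
        stim = StimulusSpec(
            modality=config.modality, p=float(p), duration=config.stimulus_duration
        )
        rec = run_trial(
            syn,
            stim,
            rng=rng,
            patient=patient,
            eye_condition=config.eye_condition,
            fp_enabled=False,
            learning=hebb,
            interrupt_on_detection=True,
            params=params,
            protocol=f"training-{config.paradigm}",
            _ctx=ctx,
        )
        log.append(rec)
        if k in config.snapshot_at:
            ctx.writeback()
            snapshots[k] = syn.copy()
    ctx.writeback()
    return syn, log, snapshots


def run_test_session(
    patient: Patient,
    synapses: SynapseSet,
    config: TestConfig,
    rng: np.random.Generator,
    *,
    params: ModelParams = DEFAULT,
    label: str = "test",
) -> tuple[list[TrialRecord], dict]:
    """Visual test session: visual-only 100 ms stimuli, learning and FP off.

    Returns the per-trial records and a summary with detection accuracy and
    triggered-saccade statistics. Trials whose detection was
    restitution-mediated are excluded from saccade counts and latencies
    (the oculomotor response was not needed for those detections).
    """
    specs = [
        StimulusSpec(modality="visual", p=p, duration=config.stimulus_duration)
        for p in config.positions
        for _ in range(config.repeats)
    ]
    res = simulate_trials(
        synapses,
        specs,
        rng=rng,
        lesion=patient,
        eye_condition=config.eye_condition,
        fp_enabled=False,
        params=params,
    )
    records = _records_from_batch(
        res,
        specs,
        patient_id=patient.id,
        protocol=f"{label}-test{config.test}",
        eye_condition=config.eye_condition,
    )
    restitution = res.detected & (res.mediated == "restitution")
    counted_saccade = res.has_saccade & ~restitution
    latencies = res.t_s[counted_saccade]
    n = len(specs)
    summary = {
        "patient": patient.id,
        "test": config.test,
        "eye_condition": config.eye_condition,
        "n_trials": n,
        "n_detected": int(res.detected.sum()),
        "accuracy_pct": 100.0 * float(res.detected.sum()) / n,
        "n_restitution": int(restitution.sum()),
        "n_saccade_mediated": int((res.mediated == "saccade").sum()),
        "n_saccades": int(counted_saccade.sum()),
        "saccade_pct": 100.0 * float(counted_saccade.sum()) / n,
        "latencies": latencies,
    }
    return records, summary
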