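"""Shared fixtures: basal connectivity, reference patients, trained cohorts.

Training-session fixtures are session-scoped because a full 300-trial
session is the expensive unit of work; every test that needs trained
weights shares them. All randomness is seeded from fixed master seeds.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from colliculus import SynapseSet, TrainingConfig, load_reference_patients
from colliculus.protocols import run_training_session

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: master seed for every deterministic fixture in the suite
MASTER_SEED = 0

#: the five reference patients with only scattered spared V1 neurons
SCATTERED_IDS = (1, 18, 5, 4, 7)


@pytest.fixture(scope="session")
def basal_synapses() -> SynapseSet:
    return SynapseSet.basal()


@pytest.fixture(scope="session")
def patients() -> dict:
    return {p.id: p for p in load_reference_patients()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def trained_A_scattered(patients):
    """Paradigm-A trained weights for the five scattered-lesion patients."""
    out = {}
    for pid in SCATTERED_IDS:
        syn, log, _ = run_training_session(
            patients[pid],
            TrainingConfig(paradigm="A"),
            np.random.default_rng(MASTER_SEED + int(pid)),
        )
        out[pid] = (syn, log)
    return out


@pytest.fixture(scope="session")
def trained_B_p19(patients):
    syn, log, _ = run_training_session(
        patients[19], TrainingConfig(paradigm="B"), np.random.default_rng(MASTER_SEED + 190)
    )
    return syn, log


@pytest.fixture(scope="session")
def trained_C_p19(patients):
    syn, log, _ = run_training_session(
        patients[19], TrainingConfig(paradigm="C"), np.random.default_rng(MASTER_SEED + 191)
    )
    return syn, log
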