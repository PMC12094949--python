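"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from musclenet import (
    SynthEmgConfig,
    chain_precision,
    generate_dataset,
    generate_weight_observations,
    preprocess_trials,
)
from musclenet.synthetic import ground_truth_for


@pytest.fixture(scope="session")
def cfg_k2():
    return SynthEmgConfig(seed=7, k_true=2)


@pytest.fixture(scope="session")
def dataset_k2(cfg_k2):
    """30 self-condition trials with two planted synergies (study size)."""
    trials, truths = generate_dataset(cfg_k2, conditions=("self",))
    return trials, truths


@pytest.fixture(scope="session")
def processed_k2(dataset_k2):
    trials, _ = dataset_k2
    return preprocess_trials(trials)


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless, artifact-free trial plus its planted ground truth."""
    from musclenet import generate_emg_trial

    cfg = SynthEmgConfig(seed=7, k_true=2, snr_db=np.inf, ecg_amplitude=0.0, drift_sd=0.0)
    return generate_emg_trial(cfg, "S01", "self", 0)


@pytest.fixture(scope="session")
def chain_obs_30():
    """30 Gaussian weight observations from an 8-node chain precision."""
    return generate_weight_observations(chain_precision(8, 0.4), 30, seed=11)


def pairs_precision(p: int, pc: float = 0.6) -> np.ndarray:
    """Disjoint strong-edge pairs: detectable even at small n."""
    T = np.eye(p)
    for i in range(0, p - 1, 2):
        T[i, i + 1] = T[i + 1, i] = -pc
    return T
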