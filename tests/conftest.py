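import numpy as np
import pytest

from msdyn.eeg import EEGRecording, STANDARD_CHANNELS
from msdyn.network import AtlasPartition, DEFAULT_NETWORKS
from msdyn.synthetic import (CohortConfig, default_ground_truth,
                             simulate_state_sequence, simulate_eeg)


@pytest.fixture(scope="session")
def ground_truth():
    """Default control/patient generating parameters (fixed seed)."""
    return default_ground_truth(CohortConfig(), seed=7)


@pytest.fixture(scope="session")
def clean_recording(ground_truth):
    """50 s noise-free EEG from the control chain, no polarity flips."""
    gt = ground_truth["control"]
    seq = simulate_state_sequence(gt, 25000, 500.0, seed=11)
    rec = simulate_eeg(gt.templates, seq, np.inf, 500.0, seed=12,
                       polarity_flips=False)
    return rec, seq


@pytest.fixture(scope="session")
def noisy_recording(ground_truth):
    """50 s EEG at SNR 5 with segment polarity flips (the realistic case)."""
    gt = ground_truth["control"]
    seq = simulate_state_sequence(gt, 25000, 500.0, seed=21)
    rec = simulate_eeg(gt.templates, seq, 5.0, 500.0, seed=22)
    return rec, seq


@pytest.fixture()
def random_recording():
    rng = np.random.default_rng(3)
    return EEGRecording(rng.standard_normal((16, 2000)) * 20.0, 500.0,
                        list(STANDARD_CHANNELS))


@pytest.fixture(scope="session")
def small_partition():
    """14-ROI partition, two ROIs per canonical network."""
    mapping = {}
    i = 0
    for net in DEFAULT_NETWORKS:
        for _ in range(2):
            i += 1
            mapping[f"ROI{i:03d}"] = net
    return AtlasPartition(mapping=mapping, networks=list(DEFAULT_NETWORKS))


@pytest.fixture(scope="session")
def small_cohort_config():
    """Desk-scale cohort: 7+7 subjects, 10 s EEG, 60 BOLD volumes.

    Seven patients is the smallest group for which the MIDAS partial
    correlations (three covariates) remain estimable.
    """
    return CohortConfig(n_patients=7, n_controls=7, eeg_duration_s=10.0,
                        bold_timepoints=60)
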