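import dataclasses

import numpy as np
import pytest

from eegdx.signal_core import Recording
from eegdx.synthcohort import CohortSpec, default_group_specs

FS = 500.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def sine(freq, duration=10.0, fs=FS, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """An 8+8-subject, 4-channel, 60 s cohort at 250 Hz: quick to generate
    while keeping the group contrasts of the default conditions."""
    mci, ad = default_group_specs()
    mci = dataclasses.replace(mci, n_subjects=8)
    ad = dataclasses.replace(ad, n_subjects=8)
    return CohortSpec(groups=(mci, ad), n_channels=4,
                      channel_labels=("C3", "C4", "Cz", "Pz"),
                      sampling_rate=250.0, duration=60.0,
                      fraction_without_second_visit=0.25, master_seed=11)


def null_cohort_spec(master_seed: int, n=8) -> CohortSpec:
    """Two groups with identical generative parameters (null contrast)."""
    mci, _ = default_group_specs()
    a = dataclasses.replace(mci, label="MCI-stable", n_subjects=n)
    b = dataclasses.replace(mci, label="AD-converter", n_subjects=n)
    return CohortSpec(groups=(a, b), n_channels=4,
                      channel_labels=("C3", "C4", "Cz", "Pz"),
                      sampling_rate=250.0, duration=60.0,
                      fraction_without_second_visit=0.25,
                      master_seed=master_seed)


@pytest.fixture(scope="session")
def noise_recording(rng):
    data = rng.standard_normal((4, int(60 * FS)))
    return Recording(data=data, sampling_rate=FS,
                     channel_labels=["C3", "C4", "Cz", "Pz"],
                     subject_id="noise", visit=1)
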