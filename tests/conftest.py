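import numpy as np
import pytest

from meowdecode import CohortSpec, cohort_frames, synth_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """A 225-respondent cohort with the default planted context valences."""
    spec = CohortSpec(n_participants=225, seed=42)
    records = synth_cohort(spec)
    participants, responses = cohort_frames(records)
    return spec, records, participants, responses


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
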