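import numpy as np
import pytest

from sepsisfuse.cohort import CohortConfig, EffectProfile, cohort_profiles, generate_ecg


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-scale cohort: 0.5 h records, 3-minute horizon unit."""
    return CohortConfig.desk_scale(n_patients=10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    profiles = cohort_profiles(small_config)
    records = {p.patient_id: generate_ecg(p, small_config) for p in profiles}
    return profiles, records


@pytest.fixture(scope="session")
def clean_config() -> CohortConfig:
    """Noise-free, modulation-free variant for exact-recovery checks."""
    return CohortConfig.desk_scale(
        n_patients=4,
        seed=11,
        effect=EffectProfile(
            ramp_hours=0.3, noise_sd=0.0,
            resp_mod_depth=0.0, wander_amp=0.0, amp_jitter_sd=0.0,
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
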