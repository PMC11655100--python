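import numpy as np
import pytest

from ecglvh.delineation import delineate_waves, detect_r_peaks
from ecglvh.synthetic import SyntheticConfig, generate_cohort, generate_record


@pytest.fixture(scope="session")
def clean_config() -> SyntheticConfig:
    """Deterministic generator: no noise, jitter or amplitude variability."""
    return SyntheticConfig(noise_sd_mv=0.0, rr_jitter_sd_s=0.0,
                           amp_scale_sd=0.0, lead_amp_jitter_sd=0.0)


@pytest.fixture(scope="session")
def clean_record(clean_config):
    """One zero-noise control record with its ground-truth fiducials."""
    return generate_record(clean_config, "control", 11)


@pytest.fixture(scope="session")
def clean_lvh_record(clean_config):
    return generate_record(clean_config, "lvh", 11)


@pytest.fixture(scope="session")
def delineated_clean(clean_record):
    """(record, truth, detected fiducials) for the zero-noise control record."""
    rec, truth = clean_record
    r_peaks = detect_r_peaks(rec.lead("II"), rec.fs)
    return rec, truth, delineate_waves(rec, r_peaks)


@pytest.fixture(scope="session")
def small_cohort():
    """20 + 20 noisy records with default class shifts."""
    return generate_cohort(20, 20, SyntheticConfig(), seed=7)
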