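import numpy as np
import pytest

from vhitdx import ImpulseParams, generate_cohort
from vhitdx.calibration import default_calibration
from vhitdx.pipeline import process_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calib():
    return default_calibration()


@pytest.fixture
def noise_free_calib():
    c = default_calibration()
    c.noise_sd = 0.0
    c.artifact_rates = {}
    return c


@pytest.fixture(scope="session")
def standard_impulse():
    return ImpulseParams(peak_velocity=200.0, duration=160.0)


@pytest.fixture(scope="session")
def small_patient_cohort():
    """A 6+6-subject HC-only patient study, generated once per session."""
    return generate_cohort({"PICA": 6, "VN": 6}, n_impulses_per_side=10,
                           canals=("HC",), seed=99)


@pytest.fixture(scope="session")
def small_patient_summaries(small_patient_cohort):
    ds = small_patient_cohort
    designated = {sid: p.designated_side for sid, p in ds.profiles.items()}
    metrics_df, summaries = process_dataset(ds.traces, ds.manifest,
                                            designated_sides=designated)
    return metrics_df, summaries
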