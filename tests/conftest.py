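import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mlpi.features import Sample

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

logging.getLogger("mlpi").setLevel(logging.ERROR)


def make_samples(rng, n, labeled, n_channels=2, patient_id="p"):
    out = []
    for _ in range(n):
        out.append(Sample(
            z=tuple(float(v) for v in rng.normal(size=n_channels)),
            pi=float(rng.uniform()),
            patient_id=patient_id,
            location=(0, 0),
            y=float(rng.uniform()) if labeled else None,
        ))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient phantom cohort shared by tuning/relief/pipeline tests."""
    from mlpi.synthetic import cohort_from_cases, generate_cohort

    cases = generate_cohort(6, seed=7, per_patient_biopsy_range=(5, 8))
    return cases, cohort_from_cases(cases)
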