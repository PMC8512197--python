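import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcgscreen.preprocess import PCGRecord, preprocess_record
from pcgscreen.synth import SynthSpec, generate_dataset, generate_record

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_pcg(samples: np.ndarray, rate: float = 2000.0, subject_id: str = "t0",
             label: str = "HC") -> PCGRecord:
    """Z-score an arbitrary signal into a PCGRecord for unit tests."""
    x = np.asarray(samples, dtype=np.float64)
    z = (x - x.mean()) / x.std()
    z = (z - z.mean()) / z.std()
    return PCGRecord(samples=z, rate=rate, subject_id=subject_id, label=label)


@pytest.fixture(scope="session")
def rhd_record():
    return generate_record(SynthSpec(murmur="systolic", seed=11, subject_id="rhd-demo"))


@pytest.fixture(scope="session")
def hc_record():
    return generate_record(SynthSpec(murmur="none", seed=12, subject_id="hc-demo"))


@pytest.fixture(scope="session")
def rhd_pcg(rhd_record):
    return preprocess_record(rhd_record)


@pytest.fixture(scope="session")
def hc_pcg(hc_record):
    return preprocess_record(hc_record)


@pytest.fixture(scope="session")
def cohort_features():
    """Feature table of the full separable synthetic cohort (124 RHD + 127 HC).

    Built once per session; this is the study-condition dataset used by the
    end-to-end checks.
    """
    from pcgscreen.features import feature_table

    records = generate_dataset(n_rhd=124, n_hc=127, seed=20240901)
    return feature_table(preprocess_record(r) for r in records)
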