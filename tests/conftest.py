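import numpy as np
import pytest

from axicost import Cohort, PatientRecord, SNType, reference_cohort


@pytest.fixture(scope="session")
def ref_cohort() -> Cohort:
    return reference_cohort()


def random_cohort(seed: int, n: int = 60) -> Cohort:
    """Small arbitrary cohort with ties and both outcomes, for oracle checks."""
    rng = np.random.default_rng(seed)
    types = list(SNType)
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i:03d}",
                sn_type=types[rng.integers(0, 3)],
                # quantized scores so threshold ties actually occur
                mskcc_score=float(rng.integers(0, 11)) / 10.0,
                n_pos_nsn=int(rng.integers(0, 2) * rng.integers(1, 5)),
            )
        )
    return Cohort(tuple(records), provenance=f"random-{seed}")


@pytest.fixture
def small_cohort() -> Cohort:
    return random_cohort(seed=7)
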