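import dataclasses

import pytest

from kexmeta.database import StudyDatabase, TreatmentMeanRecord
from kexmeta.synthetic_data import URINARY_K_INTAKE, generate


def record(record_id, study_id, n_obs=4, **kwargs):
    return TreatmentMeanRecord(record_id=record_id, study_id=study_id, n_obs=n_obs, **kwargs)


@pytest.fixture
def toy_db():
    """Six treatment means from three studies, k_ur response with k_intake."""
    recs = [
        record("A1", "A", 6, k_intake=150.0, k_ur=100.0, dmi=15.0, dietary_k=1.0),
        record("A2", "A", 6, k_intake=300.0, k_ur=200.0, dmi=15.0, dietary_k=2.0),
        record("B1", "B", 8, k_intake=200.0, k_ur=140.0),
        record("B2", "B", 8, k_intake=400.0, k_ur=260.0),
        record("C1", "C", 4, k_intake=250.0, k_ur=170.0, urine_volume=20.0),
        record("C2", "C", 4, k_intake=500.0, k_ur=330.0, urine_volume=30.0),
    ]
    return StudyDatabase(records=tuple(recs), response_name="k_ur", provenance="toy")


@pytest.fixture
def urinary_db():
    """One draw from the urinary K-intake calibration (17 studies)."""
    return generate(dataclasses.replace(URINARY_K_INTAKE, seed=7))
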