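import pytest

from sftrisk.records import PatientRecord
from sftrisk.simulate import SyntheticCohortConfig, generate_cohort


def make_record(
    age=30.0,
    tumor_size_cm=3.0,
    mitoses_per_mm2=0.0,
    ki67_li_pct=0.5,
    necrosis_pct=0.0,
    sex="female",
    location="other",
    dedifferentiation=False,
    follow_up_months=60.0,
    metastasis=False,
    time_to_metastasis_months=None,
    patient_id="P1",
):
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        location=location,
        tumor_size_cm=tumor_size_cm,
        mitoses_per_mm2=mitoses_per_mm2,
        ki67_li_pct=ki67_li_pct,
        necrosis_pct=necrosis_pct,
        dedifferentiation=dedifferentiation,
        follow_up_months=follow_up_months,
        metastasis=metastasis,
        time_to_metastasis_months=time_to_metastasis_months,
    )


@pytest.fixture(scope="session")
def cohort43():
    """Default-size synthetic cohort, fixed seed."""
    return generate_cohort(SyntheticCohortConfig(n=43, seed=1))


@pytest.fixture(scope="session")
def cohort200():
    """Larger cohort with enough events for stable survival statistics."""
    return generate_cohort(SyntheticCohortConfig(n=200, seed=2))
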