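import pytest

from scmrd.synthio import default_patient, generate_patient_sample


@pytest.fixture(scope="session")
def diagnosis_sample():
    """One default-condition diagnosis sample (2,000 cells, 5 % ADO)."""
    patient = default_patient("P1")
    matrix, antibody, truth = generate_patient_sample(
        patient, "diagnosis", 2000, seed=42
    )
    return patient, matrix, antibody, truth


@pytest.fixture(scope="session")
def remission_sample():
    patient = default_patient("P1")
    matrix, antibody, truth = generate_patient_sample(
        patient, "remission", 800, seed=43
    )
    return patient, matrix, antibody, truth
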