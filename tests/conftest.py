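import pytest

from iripred import study_data
from iripred.cohort import Cohort, PatientRecord
from iripred.panel import DEFAULT_PANEL


@pytest.fixture(scope="session")
def marginal_cohort():
    """123-patient synthetic cohort matching the published marginal tables."""
    return study_data.reconstructed_marginal_cohort()


@pytest.fixture()
def tiny_cohort():
    """Six hand-built patients exercising missing fields and both outcomes."""
    recs = [
        PatientRecord("a", (0, 0, 0, 0, 0, 2), "M", 55, 0, "training"),
        PatientRecord("b", (1, 0, 1, 1, 1, 1), "F", 64, 1, "training"),
        PatientRecord("c", (2, 0, 0, 1, 1, 1), "M", 70, 1, "training"),
        PatientRecord("d", (0, 1, 0, 0, 0, 2), "F", 48, 0, "validation"),
        PatientRecord("e", (0, -1, 1, 2, 2, 0), None, 61, 1, "validation"),
        PatientRecord("f", (0, 0, 0, 0, 0, 2), "M", 59, None, "unassigned"),
    ]
    return Cohort(DEFAULT_PANEL, recs)
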