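import pytest

from perisurf import (
    CohortSpec,
    PatientRecord,
    build_registry,
    generate_cohort,
    surface_basis,
    uniform_fraction_table,
)


@pytest.fixture(scope="session")
def uniform_registry():
    """All 40 canonical regions at the 2.5% placeholder fraction."""
    return build_registry(uniform_fraction_table())


@pytest.fixture(scope="session")
def reference_patient():
    return PatientRecord(patient_id="P-REF", height_cm=180.0, weight_kg=75.0)


@pytest.fixture(scope="session")
def reference_basis(reference_patient):
    return surface_basis(reference_patient)


@pytest.fixture(scope="session")
def small_cohort(uniform_registry):
    """Deterministic 12-patient synthetic cohort with its resection records."""
    spec = CohortSpec(n=12, seed=42, registry=uniform_registry)
    return generate_cohort(spec)
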