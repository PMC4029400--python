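import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from ctrss import (
    Cohort,
    CodeSystem,
    CohortConfig,
    Demographics,
    EAVRecord,
    Gender,
    generate,
)


def make_separable_cohort(n: int = 60, n_eligible: int = 20) -> Cohort:
    """Toy cohort where eligibility is exactly 'code L40.4 present'."""
    records = set()
    demographics = {}
    labels = {}
    for i in range(n):
        pid = f"t{i:03d}"
        eligible = i < n_eligible
        demographics[pid] = Demographics(pid, 30 + i % 40, Gender.FEMALE if i % 2 else Gender.MALE)
        labels[pid] = eligible
        if eligible:
            records.add(EAVRecord(pid, "L40.4", CodeSystem.DIAGNOSIS))
        # a label-independent background code on every third patient
        if i % 3 == 0:
            records.add(EAVRecord(pid, "5-121.1", CodeSystem.PROCEDURE))
    return Cohort(records=frozenset(records), demographics=demographics, labels=labels)


@pytest.fixture
def separable_cohort() -> Cohort:
    return make_separable_cohort()


@pytest.fixture(scope="session")
def small_synth():
    """A quick 300-patient synthetic cohort for structural tests."""
    return generate(
        CohortConfig(
            n_patients=300,
            inclusion_prevalence=0.2,
            median_code_prevalence=0.01,
            n_dx_blocks=6,
            n_proc_blocks=4,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def default_synth():
    """One cohort at the generator's default study conditions."""
    return generate(CohortConfig(seed=11))
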