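import numpy as np
import pytest

from riskcombine import synthetic
from riskcombine.gail import HazardTable
from riskcombine.io import GenotypeMatrix, SnpPanelEntry, SubjectRecord


@pytest.fixture
def small_panel() -> list[SnpPanelEntry]:
    return [
        SnpPanelEntry("rs1", "A", 1.0, 0.3),
        SnpPanelEntry("rs2", "G", 2.0, 0.5),
        SnpPanelEntry("rs3", "C", 1.2, 0.1),
    ]


@pytest.fixture
def small_genotypes(small_panel) -> GenotypeMatrix:
    dosages = np.array(
        [
            [0.0, 2.0, 1.0],
            [1.0, 0.0, np.nan],
            [2.0, 1.0, 0.0],
        ]
    )
    return GenotypeMatrix(
        subject_ids=["s1", "s2", "s3"],
        rsids=[e.rsid for e in small_panel],
        dosages=dosages,
    )


@pytest.fixture
def flat_hazards() -> HazardTable:
    bands = tuple((a, a + 5) for a in range(35, 90, 5))
    return HazardTable(
        age_bands=bands,
        incidence=tuple([0.002] * len(bands)),
        competing_mortality=tuple([0.004] * len(bands)),
    )


@pytest.fixture
def subject_reference() -> SubjectRecord:
    """All-reference-category subject (relative risk exactly 1)."""
    return SubjectRecord(
        subject_id="ref",
        status="control",
        age=45,
        n_first_degree_relatives="0",
        age_menarche=14,
        age_first_birth=19,
        n_biopsies=0,
        hyperplasia=None,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded synthetic cohort shared across read-only tests."""
    config = synthetic.SimulationConfig(seed=7)
    return synthetic.simulate_cohort(config)
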