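import numpy as np
import pandas as pd
import pytest

from cascadkit import LongitudinalScores, load_reference_cohort
from cascadkit.scoring import (
    DEFAULT_REGION_MAP,
    ClothingType,
    LesionSeverity,
    PatientAssessment,
    RegionAssessment,
)


@pytest.fixture(scope="session")
def reference_cohort() -> pd.DataFrame:
    return load_reference_cohort()


@pytest.fixture(scope="session")
def reference_scores(reference_cohort) -> LongitudinalScores:
    """The published baseline / week-12 CAS-CAD pairs as a score table."""
    matrix = pd.DataFrame(
        {
            0: reference_cohort["cascad_baseline"].to_numpy(),
            12: reference_cohort["cascad_week12"].to_numpy(),
        },
        index=reference_cohort.index.astype(str),
    )
    return LongitudinalScores("CAS-CAD", matrix)


def make_assessment(
    patient_id="P01",
    visit_week=0,
    clothing=ClothingType.TYPE1,
    severity=(1, 1, 1, 1),
    area_percent=40.0,
    nrs=5,
    iga=2,
):
    """Uniform assessment: the same severity and area on every region."""
    regions = tuple(
        RegionAssessment(r.region_id, LesionSeverity(*severity), area_percent)
        for r in DEFAULT_REGION_MAP
    )
    return PatientAssessment(patient_id, visit_week, clothing, regions, nrs, iga)


@pytest.fixture
def uniform_assessment():
    return make_assessment()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
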