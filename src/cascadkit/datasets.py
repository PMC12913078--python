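"""Published reference data bundled for worked examples and validation.

``load_reference_cohort`` returns the per-patient table of a published
16-patient cohort of chronic actinic dermatitis treated with the JAK1
inhibitor abrocitinib: demographics, disease course, treatment duration, and
the averaged two-rater CAS-CAD totals at baseline and week 12.  Summary
statistics of this table (baseline 23.65 +/- 7.86, week 12 2.41 +/- 1.85;
14/16 excellent and 2/16 good responses) are the calibration targets of the
synthetic cohort generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_cohort"]

# patient, sex, age (years), disease course (years), abrocitinib duration
# (weeks), CAS-CAD at baseline, CAS-CAD at week 12.
_REFERENCE_COHORT = [
    (1, "F", 43, 3.0, 40, 28.970, 4.235),
    (2, "F", 83, 1.0, 12, 21.610, 1.200),
    (3, "M", 57, 3.0, 24, 17.230, 4.330),
    (4, "M", 65, 4.0, 32, 27.350, 1.050),
    (5, "M", 75, 1.0, 12, 12.760, 0.410),
    (6, "M", 78, 1.0, 12, 22.945, 1.645),
    (7, "M", 61, 3.0, 24, 20.690, 0.950),
    (8, "M", 58, 10.0, 12, 12.420, 1.545),
    (9, "M", 77, 16.0, 20, 25.660, 2.105),
    (10, "M", 66, 7.0, 12, 14.300, 0.790),
    (11, "M", 69, 0.5, 12, 30.155, 1.020),
    (12, "M", 79, 2.0, 12, 38.780, 2.900),
    (13, "M", 51, 1.0, 16, 37.030, 3.445),
    (14, "M", 74, 1.0, 24, 25.780, 7.115),
    (15, "M", 76, 7.0, 12, 25.060, 4.465),
    (16, "M", 52, 10.0, 12, 17.630, 1.370),
]


def load_reference_cohort() -> pd.DataFrame:
    """The published 16-patient abrocitinib-treated CAD cohort."""
    return pd.DataFrame(
        _REFERENCE_COHORT,
        columns=[
            "patient",
            "sex",
            "age_years",
            "disease_course_years",
            "abrocitinib_weeks",
            "cascad_baseline",
            "cascad_week12",
        ],
    ).set_index("patient")
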