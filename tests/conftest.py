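import numpy as np
import pandas as pd
import pytest

from gbtm.simulate import (
    GeneratingModel,
    StudyDesign,
    default_design,
    default_generating_model,
    generate_cohort,
)


@pytest.fixture(scope="session")
def truth_model() -> GeneratingModel:
    return default_generating_model()


@pytest.fixture(scope="session")
def default_cohort(truth_model) -> pd.DataFrame:
    """One realization of the reference study layout (1805 rows)."""
    return generate_cohort(default_design(seed=20260928), truth_model)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Fast three-group cohort: 12 subjects, every 4th study day, low noise."""
    design = StudyDesign(n_subjects=12, group_sizes=(4, 4, 4),
                         observation_days=tuple(range(6, 58, 4)), n_missing=0, seed=5)
    model = GeneratingModel(sigma=0.5)
    return generate_cohort(design, model)


def subject_series(data: pd.DataFrame, subject_id) -> list:
    sub = data[data["subject_id"] == subject_id]
    return list(zip(sub["day"].to_numpy(float), sub["value"].to_numpy(float)))
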