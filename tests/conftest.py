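import numpy as np
import pandas as pd
import pytest

from twinmap.pipeline import PipelineResult, run_synthetic_stratification


def make_patient(**overrides) -> dict:
    """A complete-case good-prognosis patient row; override fields at will."""
    base = dict(
        patient_id="P0",
        age=75.0,
        bmi=25.0,
        tumor_size=20.0,
        sbr_grade=2,
        n_nodes_involved=0,
        er_percent=80.0,
        pr_percent=60.0,
        hr_positive=pd.NA,
        hemoglobin=13.4,
        lymphocytes=1.8,
        has_comorbidity=False,
        received_chemo=False,
        followup_months=72.0,
        death=False,
        relapse=False,
    )
    base.update(overrides)
    return base


def make_cohort(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"P{i}" for i in range(len(df))]
    return df


@pytest.fixture
def patient_row():
    return make_patient()


@pytest.fixture(scope="session")
def pipeline_2000() -> PipelineResult:
    """Full synthetic-cohort pipeline at the study's reference scale.

    Shared across the end-to-end and acceptance tests; n=2000 with the
    default six cluster archetypes and the package's default settings.
    """
    return run_synthetic_stratification(n=2000, seed=0)


@pytest.fixture(scope="session")
def blobs_9d():
    """Two well-separated 9D Gaussian blobs with labels."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 1.0, size=(60, 9))
    b = rng.normal(8.0, 1.0, size=(60, 9))
    X = np.vstack([a, b])
    y = np.repeat([0, 1], 60)
    return X, y
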