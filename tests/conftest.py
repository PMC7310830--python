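from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def lms_toy_path() -> Path:
    return DATA_DIR / "lms_toy.csv"


@pytest.fixture(scope="session")
def lms_toy(lms_toy_path) -> pd.DataFrame:
    return pd.read_csv(lms_toy_path)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The study-scale synthetic cohort (n=851, published marginals)."""
    from muacscreen import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec())


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Marker/status arrays of the default cohort after ingestion."""
    from muacscreen import build_records
    from muacscreen.anthropometry import records_to_frame

    records = [r for r in build_records(default_cohort)
               if r.complete and r.bmi_z is not None]
    frame = records_to_frame(records)
    return frame


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
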