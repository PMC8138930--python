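import numpy as np
import pytest

from sepkin.kinematics import cohort_kf, estimate_sepsis_position
from sepkin.pipeline import cohort_from_records
from sepkin.preprocess import run_preprocessing
from sepkin.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed drift cohort taken through the full preprocessing cascade."""
    config = SimConfig(n_positive=12, n_negative=20, length_range=(36, 70), seed=42)
    records, truth = simulate_cohort(config)
    series, report = run_preprocessing(cohort_from_records(records))
    return {"config": config, "records": records, "truth": truth,
            "series": series, "report": report}


@pytest.fixture(scope="session")
def small_kf(small_cohort):
    series = small_cohort["series"]
    positives = [s for s in series if s.label == 1]
    sepsis = estimate_sepsis_position(positives)
    return {"sepsis": sepsis, "matrices": cohort_kf(series, sepsis), "series": series}
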