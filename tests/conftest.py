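import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirserum as m

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return m.default_panel()


@pytest.fixture(scope="session")
def hemolysis_cohort(design):
    spec = m.CohortSpec(design=design, scenario="hemolysis_pairs", n_subjects=10)
    return m.generate_cohort(spec, seed=42)


@pytest.fixture(scope="session")
def tech_cohort(design):
    spec = m.CohortSpec(design=design, scenario="technical_repeat", n_subjects=3)
    return m.generate_cohort(spec, seed=7)


@pytest.fixture()
def tiny_ct():
    """3 assays x 4 samples, no missing values, hand-checkable."""
    vals = pd.DataFrame(
        [[20.0, 21.0, 20.5, 22.0],
         [25.0, 26.0, 24.0, 27.0],
         [30.0, 31.5, 29.0, 33.0]],
        index=["a1", "a2", "a3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return m.CtMatrix(vals)
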