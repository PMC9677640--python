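import pytest

from coughcohort.codebooks import default_codebooks
from coughcohort.records import StudyPeriods
from coughcohort.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def books():
    return default_codebooks()


@pytest.fixture(scope="session")
def periods():
    return StudyPeriods()


@pytest.fixture(scope="session")
def noisy_bundle():
    """A moderately sized noisy simulation shared across tests."""
    cfg = SimulationConfig(n_beneficiaries=1500, planted_p1=60, planted_p2=40)
    return generate(cfg, seed=20260301)


@pytest.fixture(scope="session")
def noisefree_planted():
    """Planted members only: every cough claim is planted, none random."""
    cfg = SimulationConfig(
        n_beneficiaries=1000,
        planted_p1=100,
        planted_p2=50,
        cough_category_rates={c: 0.0 for c in (
            "CHRONIC", "INFECTION", "ATOPIC_ALLERGIC", "CVA", "POSTINFECTIOUS", "OTHER"
        )},
    )
    return generate(cfg, seed=42)
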