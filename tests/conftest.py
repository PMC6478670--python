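import pytest
from hypothesis import HealthCheck, settings

import polyrisk as pr

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_table() -> pr.FactorTable:
    return pr.default_factor_table()


@pytest.fixture(scope="session")
def scoring_table(default_table) -> pr.ScoringTable:
    return pr.build_scoring_table(default_table)


@pytest.fixture(scope="session")
def urbanicity() -> pr.RiskFactor:
    """The two-level worked reference factor: RR 2.2, 73.6% exposed."""
    return pr.RiskFactor(
        name="Urbanicity",
        levels=(
            pr.FactorLevel("Yes", 2.2, 0.736),
            pr.FactorLevel("No", 1.0, 0.264),
        ),
        baseline_label="No",
    )


@pytest.fixture(scope="session")
def trauma() -> pr.RiskFactor:
    return pr.RiskFactor(
        name="Childhood trauma",
        levels=(
            pr.FactorLevel("Yes", 2.87, 0.109),
            pr.FactorLevel("No", 1.0, 0.891),
        ),
        baseline_label="No",
    )
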