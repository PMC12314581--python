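import pytest

from homeval.synthetic import (
    SyntheticConfig,
    WorkedExample,
    generate_benchmark,
    generate_figure2_fixture,
)


@pytest.fixture(scope="session")
def fig2() -> WorkedExample:
    return generate_figure2_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort (72 domains) shared across tests."""
    return generate_benchmark(SyntheticConfig(seed=11))
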