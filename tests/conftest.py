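from pathlib import Path

import pytest

from eldercare_game import baseline_scenario, random_scenarios
from eldercare_game.model import StatePoint
from eldercare_game.scenarios import ScenarioSpec

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def baseline():
    return baseline_scenario()


@pytest.fixture()
def x0():
    return StatePoint(x1=1.0, x2=1.0)


@pytest.fixture(scope="session")
def random_batch():
    """Fifty seeded admissible scenarios shared across property tests."""
    return random_scenarios(ScenarioSpec(seed=1234, count=50))


@pytest.fixture(scope="session")
def fixture_dir():
    return FIXTURES
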