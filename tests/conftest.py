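import numpy as np
import pandas as pd
import pytest

from mizscape.synthetic import DiveScenario, SurveyScenario, gen_echogram_survey

# Canonical seed for every seeded test (the campaign start date).
SEED = 20141214


@pytest.fixture(scope="session")
def small_survey():
    """A reduced survey (quick to generate) with the default prey structure."""
    scn = SurveyScenario(
        n_edge_stations=10, n_interior_stations=18, pings_per_station=300, rng_seed=SEED
    )
    grids, stations, truth = gen_echogram_survey(scn)
    return scn, grids, stations, truth


@pytest.fixture(scope="session")
def default_survey():
    """The full default survey: 30 edge + 54 interior deployments."""
    scn = SurveyScenario(rng_seed=SEED)
    grids, stations, truth = gen_echogram_survey(scn)
    return scn, grids, stations, truth


@pytest.fixture(scope="session")
def small_dive_scenario():
    return DiveScenario(
        n_penguins=3, trips_per_penguin=1, dives_per_trip=12, rng_seed=SEED
    )
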