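import numpy as np
import pandas as pd
import pytest

from frmodules import study_design_scenario, response
from frmodules.simulate import (
    PartialCurve,
    PreyScenario,
    SimulationScenario,
    TreatmentCoding,
)

LADDER = (2, 4, 6, 8, 10, 20, 30)

#: published within-module base-level point estimates (isopod prey)
BASE_A, BASE_H = 0.981, 0.307


def single_cell_records(a, h, ladder=LADDER, reps=4, seed=0, t=1.0):
    """Minimal one-cell trial table: binomial kills around the Rogers curve."""
    rng = np.random.default_rng(seed)
    rows = []
    for n0 in ladder:
        p = response.rogers_expected_eaten(a, h, n0, t) / n0
        for _ in range(reps):
            rows.append({"density": int(n0), "killed": int(rng.binomial(n0, p))})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study_scenario():
    return study_design_scenario(seed=101)


@pytest.fixture(scope="session")
def study_dataset(study_scenario):
    from frmodules import simulate_dataset

    return simulate_dataset(study_scenario)


@pytest.fixture
def one_prey_scenario():
    """Single prey species at the published base values, amphipod effect on h."""
    prey = {
        "A_aquaticus": PreyScenario(
            attack=TreatmentCoding(BASE_A),
            handling=TreatmentCoding(BASE_H, {"amphipod": -0.178}),
            partial=PartialCurve(pmax=0.3, midpoint=10.0, steepness=0.3),
        )
    }
    return SimulationScenario(prey=prey, seed=11)
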