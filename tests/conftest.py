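import numpy as np
import pytest

import bdat
from bdat import Condition
from bdat.simulate import SimulationConfig, simulate_study1_dataset


@pytest.fixture(scope="session")
def params():
    return bdat.default_params()


@pytest.fixture(scope="session")
def default_bank():
    return bdat.build_item_bank()


@pytest.fixture(scope="session")
def study1_500():
    """One fixed-design simulated calibration dataset at n = 500."""
    return simulate_study1_dataset(SimulationConfig(n_respondents=500, seed=101))


@pytest.fixture(scope="session")
def fit_on_500(study1_500, params):
    truth = params[Condition.ON]
    return bdat.fit_explanatory(study1_500, Condition.ON, g=truth.g, u=truth.u)


@pytest.fixture(scope="session")
def fit_off_500(study1_500, params):
    truth = params[Condition.OFF]
    return bdat.fit_explanatory(study1_500, Condition.OFF, g=truth.g, u=truth.u)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small crossed dataset: 10 participants x 5 tracks, OFF condition.

    Small enough for the Monte-Carlo integration oracle to be feasible.
    """
    rng = np.random.default_rng(7)
    p = bdat.default_params()[Condition.OFF]
    levels = bdat.displacement_levels()
    rows = []
    for pid in range(10):
        theta = rng.normal()
        for track in range(1, 6):
            lvl = int(rng.integers(1, 8))
            late = bool(rng.integers(2))
            beat = int(rng.choice([3, 4]))
            strength = 1.0 if beat == 3 else 0.0
            eta = (p.beta["intercept"] + p.beta["displacement"] * lvl
                   + p.beta["direction"] * late + p.beta["strength"] * strength
                   + p.beta["interaction"] * late * strength
                   + theta * p.sigma_person)
            prob = p.g + (p.u - p.g) / (1 + np.exp(-eta))
            rows.append({
                "participant_id": pid, "track_id": track, "condition": "OFF",
                "target_beat": beat,
                "direction": "late" if late else "early",
                "displacement_level": lvl, "displacement": levels[lvl - 1],
                "response": int(rng.random() < prob),
            })
    import pandas as pd
    return pd.DataFrame(rows)
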