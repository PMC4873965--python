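import numpy as np
import pandas as pd
import pytest

from allomsel.simulate import SimConfig, simulate_experiment

#: a reduced experiment for unit tests where only structure matters
SMALL_CONFIG = SimConfig(
    seed=3, n_generations=4, n_measured_selected=60, n_measured_control=40,
    n_select=20, n_sires_expected=15.0, fry_per_sire_mean=8.0,
    n_founder_females=60,
)


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale simulated experiment (9 generations, default sizes)."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    return simulate_experiment(SMALL_CONFIG)


def morph_from_logpoints(points, line="control", replicate="A", generation=1):
    """Build a male morph table whose log10(mm) coordinates are ``points``."""
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame({
        "replicate": replicate,
        "line": line,
        "generation": generation,
        "fish_id": [f"f{i:03d}" for i in range(len(pts))],
        "sex": "male",
        "sl_mm": 10.0 ** pts[:, 0],
        "gono_mm": 10.0 ** pts[:, 1],
    })
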