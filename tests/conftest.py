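import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from barscreen.screen_core import WELL_COLUMNS, summarize_pools
from barscreen.synthetic_data import ScreenSimConfig, simulate_screen

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_wells(rows):
    """Rows of (plate, well, kind, pool, firefly, renilla, replicate)."""
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


@pytest.fixture
def small_plate():
    """One plate: 4 identical negative controls (ratio 2.0), pool PA with
    ratios {0.8, 1.0, 1.2} and pool PB whose wells equal the controls."""
    rows = [
        ("PL1", f"A{i + 1:02d}", "negative_control", None, 2000.0, 1000.0, i + 1)
        for i in range(4)
    ]
    for i, f in enumerate([800.0, 1000.0, 1200.0]):
        rows.append(("PL1", f"B{i + 1:02d}", "pool", "PA", f, 1000.0, i + 1))
    for i in range(3):
        rows.append(("PL1", f"C{i + 1:02d}", "pool", "PB", 2000.0, 1000.0, i + 1))
    return make_wells(rows)


@pytest.fixture(scope="session")
def sim_screen_seed7():
    """Default desk-scale simulated screen, seed 7; shared across tests."""
    return simulate_screen(ScreenSimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_summaries_seed7(sim_screen_seed7):
    wells, annotations, _ = sim_screen_seed7
    return summarize_pools(wells, annotations, seed=7)


@pytest.fixture(scope="session")
def control_log2_ratios():
    """8 negative-control log2 ratios drawn N(0, 0.2^2), fixed seed."""
    return np.random.default_rng(11).normal(0.0, 0.2, size=8)
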