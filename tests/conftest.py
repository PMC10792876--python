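import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sdyburden as s

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> s.SimulationConfig:
    """A scaled-down null study used by many unit tests."""
    return s.SimulationConfig(
        n_genes=400,
        n_cases=60,
        n_controls=60,
        panel_specs=(s.PanelSpec("panel_a", 40),),
        seed=2027,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> s.SimulatedStudy:
    return s.simulate_study(small_config)


@pytest.fixture(scope="session")
def toy_universe() -> s.GeneUniverse:
    """Six genes with hand-checkable burden ratios."""
    return s.GeneUniverse.from_entries(
        [
            ("ALPHA", 1000, 50),  # ratio 0.05
            ("BETA", 2000, 50),   # 0.025
            ("GAMMA", 500, 0),    # 0.0
            ("DELTA", 1000, 100), # 0.1
            ("EPSI", 4000, 100),  # 0.025
            ("ZETA", 800, 40),    # 0.05
        ]
    )


@pytest.fixture()
def plp_example():
    from sdyburden.examples import load_plp_example

    return load_plp_example()
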