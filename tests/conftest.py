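import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import coralstress as cs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

CONTROLS = list(cs.DEFAULT_NORMALIZATION_CONTROLS)


def quantify_preset(config, include_controls=False):
    """Simulate a scenario and run it through quantification with the
    generator's true efficiencies. Returns (raw CaMatrix, normalized
    CaMatrix or None, Truth)."""
    cp, truth = cs.simulate_experiment(config)
    ca = cs.aggregate_duplicates(cp, config.efficiency_map())
    controls = [g for g in CONTROLS if g in ca.values.columns]
    norm = None
    if controls:
        norm = cs.normalize_ca(ca, controls, include_controls=include_controls)
    return ca, norm, truth


@pytest.fixture(scope="session")
def exp1_quantified():
    config = cs.preset_scenario("exp1", seed=20240901)
    return config, quantify_preset(config)


@pytest.fixture
def small_ca():
    """4 samples x 3 genes with a hand-checkable structure."""
    values = pd.DataFrame(
        {"g1": [0.0, 1.0, 2.0, 3.0],
         "g2": [1.0, 2.0, 3.0, 4.0],
         "g3": [0.0, 2.0, 1.0, 3.0]},
        index=["s1", "s2", "s3", "s4"],
    )
    return cs.CaMatrix(values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
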