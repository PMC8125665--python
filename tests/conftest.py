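import numpy as np
import pytest

from csfext import (
    DEFAULT_DENSITY_TABLE,
    SEVERITY_PRESETS,
    ComponentTruth,
    FractionationCondition,
    SimulationConfig,
    generate_design,
    load_l16_reference,
)


@pytest.fixture(scope="session")
def l16():
    """Packaged 16-run reference campaign (percent columns)."""
    return load_l16_reference()


@pytest.fixture(scope="session")
def l16_conds(l16):
    return [
        FractionationCondition.from_lab_units(r.temperature_C, r.fa_wt_percent, r.time_h)
        for r in l16.itertuples()
    ]


@pytest.fixture
def arr_table1():
    return SEVERITY_PRESETS["arrhenius-table1"]


@pytest.fixture
def log_table1():
    return SEVERITY_PRESETS["logistic-table1"]


@pytest.fixture
def pooled_truth():
    """Ground truth of the pooled xylan-plus-lignin reference fit."""
    return ComponentTruth("arrhenius", 14.54, 12.10, 0.1446, -5.5595)


@pytest.fixture
def density():
    return DEFAULT_DENSITY_TABLE


@pytest.fixture
def noiseless_config(pooled_truth):
    return SimulationConfig(
        truth={"xylan_plus_lignin": pooled_truth}, noise_sigma=0.0, seed=123
    )


@pytest.fixture
def noiseless_dataset(noiseless_config):
    from csfext import simulate_alpha

    conds = generate_design(noiseless_config)
    return simulate_alpha(conds, noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
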