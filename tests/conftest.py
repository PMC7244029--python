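import numpy as np
import pytest

from agedeg.synthetic import TimeSeriesConfig, TwoGroupConfig, generate_timeseries, generate_two_group


@pytest.fixture(scope="session")
def planted_two_group():
    """Small well-separated two-group dataset with strong planted effects."""
    cfg = TwoGroupConfig(
        n_probes=600,
        n_per_group=5,
        frac_absent=0.3,
        frac_deg=0.1,
        effect_size=3.0,
        noise_sd=0.3,
        seed=11,
    )
    eset, truth = generate_two_group(cfg)
    return cfg, eset, truth


@pytest.fixture(scope="session")
def planted_timeseries():
    cfg = TimeSeriesConfig(n_genes=300, frac_up=0.1, frac_down=0.1, noise_sd=0.2, seed=7)
    matrix, truth = generate_timeseries(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
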