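import dataclasses

import pytest

from coldpool import synthetic


@pytest.fixture(scope="session")
def tiny_config() -> synthetic.SyntheticConfig:
    """A two-week, 2x2x4 study small enough for exhaustive checks."""
    return synthetic.SyntheticConfig(
        seed=11,
        n_sites=2,
        transects_per_site=2,
        plots_per_transect=4,
        elevation_spans_m=(90.0, 200.0),
        start="2021-10-01 00:00",
        end="2021-10-14 23:00",
        inversion_prob=0.3,
        noise_sd=0.15,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    design = synthetic.gen_design(tiny_config)
    temps = synthetic.gen_temperatures(design, tiny_config)
    return design, temps


@pytest.fixture(scope="session")
def noiseless_config(tiny_config) -> synthetic.SyntheticConfig:
    return dataclasses.replace(tiny_config, noise_sd=0.0)
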