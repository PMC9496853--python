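import numpy as np
import pytest

from coexdiff.simulate import SimulationConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study():
    """A small two-dataset study with a planted DcoE+DE module and hubs."""
    config = SimulationConfig(
        n_genes=200,
        module_sizes=(60, 60),
        samples_per_condition={"ds1": (30, 30), "ds2": (30, 30)},
        base_corr=0.5,
        dcoe_corr=0.8,
        dcoe_module_ids=(0,),
        de_shift=0.8,
        de_module_ids=(0,),
        hub_genes_per_module=3,
        hub_loading=0.95,
        seed=42,
    )
    return generate_study(config)
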