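import numpy as np
import pytest

from mapsd.synthetic import SyntheticSpec, generate_inputs, worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def planted_inputs():
    """ER background with a dense brain-planted module holding all seeds."""
    spec = SyntheticSpec(
        n_nodes=200, er_p=0.02, module_size=25, module_edge_p=0.6,
        n_seed_genes=20, n_columns=10, n_brain_columns=2, rng_seed=1,
    )
    return generate_inputs(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
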