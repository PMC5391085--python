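import numpy as np
import pytest

from allelink.synthetic import SimConfig, build_scenario, emit_panel


@pytest.fixture(scope="session")
def small_scenario():
    """20-sample, 8-block world with strong planted effects."""
    return build_scenario(SimConfig(n_samples=20, n_tags=8, seed=11))


@pytest.fixture(scope="session")
def small_pairs(small_scenario):
    return small_scenario.mapping_inputs().build()


@pytest.fixture(scope="session")
def emitted_panel(tmp_path_factory):
    """The same world written to disk in standard formats."""
    outdir = tmp_path_factory.mktemp("panel")
    cfg = SimConfig(n_samples=20, n_tags=8, seed=11)
    scenario, paths = emit_panel(cfg, outdir)
    return scenario, paths, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
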