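import numpy as np
import pytest

from srnakit.novel import EnergyModel
from srnakit.simulate import SimulationConfig, gen_libraries, gen_references


@pytest.fixture(scope="session")
def energy_model():
    return EnergyModel.default()


@pytest.fixture(scope="session")
def sim_small():
    """A small synthetic dataset shared across tests (references + reads)."""
    cfg = SimulationConfig(seed=11, library_size=30_000)
    rng = np.random.default_rng(cfg.seed)
    refs, truth = gen_references(cfg, rng)
    reads_na, reads_da = gen_libraries(cfg, refs, truth, rng)
    return cfg, refs, truth, reads_na, reads_da


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """The same small dataset written to disk for CLI tests."""
    from srnakit.simulate import write_all
    out = tmp_path_factory.mktemp("simdata")
    cfg = SimulationConfig(seed=11, library_size=30_000)
    refs, truth = write_all(cfg, str(out))
    return out, cfg, refs, truth
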