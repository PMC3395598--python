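import numpy as np
import pytest
from hypothesis import settings

from icepop.simulate import preset, simulate_dual_reporter, simulate_population

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def wildtype_pop():
    """Mid-size wild-type population: ~3% ON via the sigma-factor tail."""
    return simulate_population(preset("wildtype", n_cells=20_000, seed=11))


@pytest.fixture(scope="session")
def dual_sample():
    """Paired reporters at the shapes whose noise truths are ~0.55/0.55."""
    return simulate_dual_reporter(50_000, sigma_E=0.5164, sigma_I=0.4542, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
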