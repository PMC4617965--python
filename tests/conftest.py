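import logging

import numpy as np
import pytest

from ripnet.simulate import default_config, simulate_all

logging.getLogger("ripnet").setLevel(logging.ERROR)
logging.getLogger("ripnet.idr").setLevel(logging.ERROR)
for name in ("ripnet.diffbind", "ripnet.simulate", "ripnet.annotation"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    """Small seeded fixture shared across unit tests."""
    return simulate_all(default_config(1, n_genes=120))


@pytest.fixture(scope="session")
def strong_bundle():
    """Deep-count fixture with strong planted fold changes (FC >= 2)."""
    return simulate_all(
        default_config(2, n_genes=150, fc_min=2.0, mu_floor=60.0, log_mu_loc=5.5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
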