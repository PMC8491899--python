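import numpy as np
import pytest

from zicopula import FixtureSpec, make_model, make_template_table


@pytest.fixture(scope="session")
def dense_small():
    """Tiny ground-truth community (p=8) with known strong correlations."""
    return make_model(FixtureSpec(p=8, n=0 + 2, regime="dense_small", seed=11))


@pytest.fixture(scope="session")
def dense_small_table():
    """Ground-truth model plus a simulated counts table (p=8, n=400)."""
    spec = FixtureSpec(p=8, n=400, regime="dense_small", seed=11)
    model, table, sim = make_template_table(spec)
    return model, table, sim


@pytest.fixture(scope="session")
def gut_model():
    """Mid-size gut-like community used by spike-in and harness tests."""
    return make_model(FixtureSpec(p=50, n=2, regime="gut_like", seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(202409)
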