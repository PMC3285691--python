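import numpy as np
import pytest

import tobaccosim as ts
from tobaccosim import scenarios

HORIZON = 30


@pytest.fixture(scope="session")
def fixture_bundle():
    """Small pinned bundle: ages 0..50, 3 quit classes, 2 diseases."""
    return ts.fixture_bundle()


@pytest.fixture(scope="session")
def dutch_bundle():
    """Full-size synthetic bundle with Dutch-like structure."""
    return ts.generate_bundle(seed=1)


@pytest.fixture(scope="session")
def max_runs(dutch_bundle):
    """Reference plus the three maximum-variant scenario runs, 30 years."""
    runs = {"reference": ts.run_projection(dutch_bundle, horizon=HORIZON)}
    for name in ("table1_max_cessation", "table1_max_initiation",
                 "table1_max_price"):
        runs[name] = ts.run_projection(
            dutch_bundle, scenarios.get_preset(name), horizon=HORIZON)
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
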