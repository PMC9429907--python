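import numpy as np
import pandas as pd
import pytest

from sporesigma import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def logistic_plate():
    """Noise-free plate where every infected well is c=0.4 of the control."""
    t = np.arange(0, 16.25, 0.25)
    control = 1.2 / (1 + (1.2 / 0.05 - 1) * np.exp(-1.4 * t))
    rows = []
    for moi, c in [(0.0, 1.0), (0.01, 0.4), (0.1, 0.4), (1.0, 0.4), (10.0, 0.4)]:
        for ti, od in zip(t, control * c):
            rows.append((f"w{moi:g}", moi, "r1", ti, od))
    return pd.DataFrame(rows, columns=["well", "moi", "replicate", "time_h", "od600"])


@pytest.fixture(scope="session")
def flow_sample():
    """One 20k-event cloud with 5% doublets, 5% noise, planted f=0.3."""
    return synthetic.gen_flow_events(20_000, 0.3, seed=7)
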