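import numpy as np
import pandas as pd
import pytest

from nestedcc import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic population shared by read-only tests."""
    cfg = SimulationConfig(n_patients=4000, seed=42)
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_binary_strata(rng, n_strata, stratum_size, p_case_exposed, p_ctrl_exposed):
    """Random 1:(m-1) matched strata with one binary exposure column."""
    X, y, s = [], [], []
    for i in range(n_strata):
        X.append([float(rng.random() < p_case_exposed)])
        y.append(1.0)
        s.append(i)
        for _ in range(stratum_size - 1):
            X.append([float(rng.random() < p_ctrl_exposed)])
            y.append(0.0)
            s.append(i)
    return np.array(X), np.array(y), np.array(s)
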