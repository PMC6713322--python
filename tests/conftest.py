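import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sgrnet

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_extrapolation_warnings():
    # extrapolation warnings are expected all over cross-range tests
    logging.getLogger("sgrnet.growth_metrics").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def juvenile_data():
    """400 synthetic juveniles from the default preset and truth."""
    return sgrnet.generate_dataset(sgrnet.PRESETS["juvenile"], n=400, seed=11)


@pytest.fixture(scope="session")
def small_data():
    """A small deterministic hand-built dataset (no noise column games)."""
    rng = np.random.default_rng(42)
    n = 40
    df = pd.DataFrame({
        "weight_g": rng.uniform(10, 60, n),
        "tc_ratio": rng.uniform(1.0, 8.0, n),
        "cf": rng.uniform(0.9, 1.5, n),
    })
    df["sgr"] = sgrnet.true_sgr(df["weight_g"], df["tc_ratio"], df["cf"])
    return sgrnet.FishDataset(df, label="small")


@pytest.fixture(scope="session")
def trained_model(juvenile_data):
    train, _ = sgrnet.split_train_test(juvenile_data, 0.15, seed=11)
    return sgrnet.train_model(train, sgrnet.INPUT_SETS[-1],
                              sgrnet.NetConfig(lam=0.3), seed=11)
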