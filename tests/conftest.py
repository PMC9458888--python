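import numpy as np
import pytest

from diaryreact import designs, preprocess, simulate


@pytest.fixture(scope="session")
def na_truth():
    return designs.negative_affect_truth()


@pytest.fixture(scope="session")
def na_dataset(na_truth):
    """One default-sized negative-affect dataset with known truth."""
    config = designs.default_config(na_truth)
    table, params = simulate.simulate_dataset(config, seed=20260901)
    return table, params


@pytest.fixture(scope="session")
def na_frame(na_dataset):
    table, params = na_dataset
    return preprocess.build_model_frame(
        table, params.design, outcome_moments=params.outcome_moments
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
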