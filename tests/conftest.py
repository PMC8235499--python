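import numpy as np
import pandas as pd
import pytest

from mircodereg.pipeline import PipelineConfig, run_pipeline
from mircodereg.synthetic import SyntheticConfig, generate_multiseries


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic configuration for fast structural tests."""
    return SyntheticConfig(
        n_series=3, features_per_series=30, shared_features=15,
        n_tumor=12, n_control=8, n_old_decoys=2, seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_multiseries(small_config)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default study conditions."""
    return run_pipeline(PipelineConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_matrix():
    """6x4 matrix with NaN holes and a known replicate structure."""
    return pd.DataFrame(
        [[2.0, 4.0, 1.0, 3.0],
         [4.0, np.nan, 2.0, 6.0],
         [1.0, 1.0, 1.0, 1.0],
         [np.nan, 5.0, 3.0, 2.0],
         [6.0, 2.0, np.nan, 4.0],
         [3.0, 3.0, 3.0, np.nan]],
        index=["A", "A", "B", "B", "C", "D"],
        columns=["s1", "s2", "s3", "s4"],
    )
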