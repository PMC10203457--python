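import numpy as np
import pandas as pd
import pytest

from phenodrought import SyntheticTrialConfig, aggregate_means, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One noisy synthetic screen (15 lines, 2 reps, 8% CV), seed 7."""
    obs, truth = generate_trial(SyntheticTrialConfig(seed=7))
    return obs, truth


@pytest.fixture(scope="session")
def noiseless_trial():
    obs, truth = generate_trial(SyntheticTrialConfig(noise_cv=0.0, seed=7))
    return obs, truth


@pytest.fixture(scope="session")
def default_matrix(default_trial):
    obs, _ = default_trial
    return aggregate_means(obs)


@pytest.fixture()
def obs_csv(tmp_path, default_trial):
    """Observation table round-tripped through a CSV on disk."""
    obs, _ = default_trial
    path = tmp_path / "obs.csv"
    obs.to_csv(path, index=False)
    return path
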