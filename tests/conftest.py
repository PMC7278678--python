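import numpy as np
import pytest

from roastcal.pipeline import fit_preprocessor
from roastcal.synthetic import CampaignConfig, simulate_campaign


@pytest.fixture(scope="session")
def default_config():
    return CampaignConfig(seed=1)


@pytest.fixture(scope="session")
def campaign84(default_config):
    """Default synthetic campaign: 84 roasts at 248 nm, fixed seed."""
    return simulate_campaign(default_config)


@pytest.fixture(scope="session")
def campaign_small():
    return simulate_campaign(CampaignConfig(seed=7, n_roasts=24))


@pytest.fixture(scope="session")
def campaign_zero_noise():
    cfg = CampaignConfig(seed=3, n_roasts=20).zero_noise()
    return simulate_campaign(cfg)


@pytest.fixture(scope="session")
def descriptors_small(campaign_small):
    X, state = fit_preprocessor(campaign_small)
    y_col = np.array([r.colorette for r in campaign_small])
    y_fc = np.array([r.fc_value for r in campaign_small])
    return X, state, y_col, y_fc


@pytest.fixture(scope="session")
def descriptors_zero_noise(campaign_zero_noise):
    X, state = fit_preprocessor(campaign_zero_noise)
    y_col = np.array([r.colorette for r in campaign_zero_noise])
    y_fc = np.array([r.fc_value for r in campaign_zero_noise])
    return X, state, y_col, y_fc


def make_linear_problem(n, p, rank, noise_sd, seed):
    """Random low-rank X with y exactly linear in its latent factors."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, rank))
    load = rng.normal(size=(rank, p))
    X = scores @ load
    w = rng.normal(size=rank)
    y = scores @ w + 5.0
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)
        y = y + rng.normal(0.0, noise_sd, n)
    return X - X.mean(axis=0), y
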