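"""Shared fixtures: small seeded synthetic data sets."""

import numpy as np
import pytest

from shortscale import SimulationConfig, SubsetScorer, simulate_responses


@pytest.fixture(scope="session")
def pool10():
    """10 well-behaved items (no guessing), n=800, with two covariates."""
    config = SimulationConfig(
        n_persons=800,
        n_items=10,
        loading_spec=np.linspace(0.35, 0.8, 10),
        difficulty_spec=np.linspace(0.35, 0.85, 10),
        guessing=0.0,
        covariate_spec=(("crit_a", 0.5), ("crit_b", 0.1)),
        seed=42,
    )
    return simulate_responses(config)


@pytest.fixture(scope="session")
def pool10_scorer(pool10):
    data, covariates, _ = pool10
    scorer = SubsetScorer(data, covariates)
    scorer.corr  # precompute the tetrachoric matrix once per session
    return scorer
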