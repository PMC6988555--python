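import numpy as np
import pytest

import overlapshift as o
from overlapshift.inference import InferenceConfig, fit


@pytest.fixture(scope="session")
def grid10():
    return o.build_grid(10, 10)


@pytest.fixture(scope="session")
def adjacency10(grid10):
    return o.build_adjacency(grid10, "queen")


@pytest.fixture(scope="session")
def grid30():
    return o.build_grid(30, 30)


@pytest.fixture(scope="session")
def joint_synthetic(grid30):
    """One seeded joint hurdle-gamma dataset with its generative truth."""
    covs = o.simulate_covariates(grid30, ["PEA", "NPP"], seed=1000)
    covmap = {c.name: c for c in covs}
    truth = o.default_truth(grid30, ("PEA", "NPP"), seed=2000)
    species = o.simulate_joint_species(grid30, covmap, truth, seed=3000)
    return covmap, truth, species


@pytest.fixture(scope="session")
def joint_fit(joint_synthetic):
    """A fitted joint model shared across unit tests (reduced budget)."""
    covmap, truth, species = joint_synthetic
    spec = o.ModelSpec(species=("predator", "prey"), covariates=("PEA", "NPP"),
                       family={"predator": "gamma", "prey": "hurdle-gamma"})
    cfg = InferenceConfig(seed=0, max_opt_evals=150, n_samples=100,
                          estimate_hyperparameter_uncertainty=False)
    return fit(spec, species, covmap, cfg)
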