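import numpy as np
import pytest

from normsynth import FixtureSpec, RunConfig, make_latent_normal_sample
from normsynth.pca import fit_model, synthesize


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    # desk-scale sizes: enough structure to exercise every stage in seconds
    return RunConfig(
        seed=7,
        de_pop_size=20,
        de_generations=5,
        kde_augment_n=20_000,
        map_normal_n=20_000,
        sp_size=20_000,
        n_eval_reps=30,
        n_projections=100,
    )


@pytest.fixture(scope="session")
def small_latent():
    spec = FixtureSpec(
        n=200, d=4, seed=7,
        marginal_transforms=("exp", "identity", "logistic", "round"),
    )
    sample, truth = make_latent_normal_sample(spec)
    return sample, truth


@pytest.fixture(scope="session")
def fitted_tiny(small_latent, tiny_config):
    """One fitted model + synthetic population shared across tests."""
    sample, _ = small_latent
    archive = fit_model(sample, tiny_config)
    sp = synthesize(archive, tiny_config.sp_size)
    return sample, archive, sp
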