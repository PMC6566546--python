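import numpy as np
import pytest

from beetmsi.synthetic_seeds import (
    SimulationConfig,
    generate_dataset,
    make_default_profiles,
)


@pytest.fixture(scope="session")
def profiles():
    return make_default_profiles(0)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_seeds_per_class=3, n_varieties=4, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """3 seeds/class, both sides: 30 stacks with ground truth."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def noiseless_dataset():
    cfg = SimulationConfig(
        n_seeds_per_class=2, n_varieties=2, noise_sd=0.0, rng_seed=5
    )
    return generate_dataset(cfg), cfg


def render_single(profile, *, noise_sd=1.0, rng_seed=3, side="ventral"):
    """Helper: render one seed side with a fresh rng."""
    from beetmsi.synthetic_seeds import render_seed

    cfg = SimulationConfig(noise_sd=noise_sd, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    return render_seed(profile, side, np.zeros(19), cfg, 0, rng)
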