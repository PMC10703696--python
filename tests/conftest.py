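import pytest

from ecdna.simulate import (
    FishSimConfig,
    FragmentSimConfig,
    gen_fish_image,
    gen_fragments,
)


@pytest.fixture(scope="session")
def small_frag_sim():
    """Small snATAC simulation shared across caller tests."""
    return gen_fragments(
        FragmentSimConfig(n_cells=150, background_mean=1_500, seed=5)
    )


@pytest.fixture(scope="session")
def fish_sim_clean():
    return gen_fish_image(FishSimConfig(seed=3))


@pytest.fixture(scope="session")
def fish_sim_noisy():
    return gen_fish_image(FishSimConfig(seed=4, noise_sd=5.0))
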