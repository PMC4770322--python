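import numpy as np
import pytest

from biomemap import pipeline, synthetic


@pytest.fixture(scope="session")
def noiseless_sample():
    """Full pipeline run with zero noise, identity warp, bare derivatives."""
    return pipeline.run_sample(
        seed=2,
        noise_reflectance=0.0,
        noise_fluor=0.0,
        warp="identity",
        smoothing=None,
        gcp_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def noisy_sample():
    """Default stated world: lower shore / medium biomass, 2% noise, warp."""
    return pipeline.run_sample(seed=1)


@pytest.fixture(scope="session")
def small_truth():
    return synthetic.make_scene(seed=3, shape=(48, 48), warp="identity")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
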