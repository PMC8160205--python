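import numpy as np
import pytest

import rhodolith as rh


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Small noise-free study bundle shared by the end-to-end tests."""
    return rh.simulate_study(seed=11, noise_scale=0.0, n_volumes=2,
                             n_incubation_reps=3, include_titrations=True)


@pytest.fixture(scope="session")
def bundle_dir(noise_free_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    from rhodolith.io import write_bundle
    write_bundle(noise_free_bundle, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
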