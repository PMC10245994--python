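"""Shared fixtures: small synthetic study generated once per session."""

import numpy as np
import pytest

from seedgrad import synthetic


@pytest.fixture(scope="session")
def sphere3():
    return synthetic.make_sphere_surface(3)

@pytest.fixture(scope="session")
def sphere4_masked():
    return synthetic.make_sphere_surface(4, medial_wall_fraction=0.05)


@pytest.fixture(scope="session")
def parcellation100(sphere4_masked):
    return synthetic.make_parcellation(sphere4_masked, 100, seed=1)


@pytest.fixture(scope="session")
def seed_region125():
    return synthetic.make_seed_region((5, 5, 5), subregion_split=0.4, seed=1)


@pytest.fixture(scope="session")
def truth_coupled(seed_region125, parcellation100):
    return synthetic.make_truth(
        seed_region125, parcellation100, intermodal_coupling=1.0, seed=1
    )


@pytest.fixture(scope="session")
def noisefree_connectomes(seed_region125, parcellation100, truth_coupled):
    s, f, _ = synthetic.simulate_connectomes(
        seed_region125, parcellation100, truth_coupled, noise_sd=0.0, n_subjects=1
    )
    return s[0], f[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
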