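import numpy as np
import pytest

from wingshape import synthetic
from wingshape.superimposition import LandmarkConfiguration, gpa_align


@pytest.fixture(scope="session")
def template():
    return synthetic.wing_template()


@pytest.fixture(scope="session")
def small_bundle():
    """8 taxa, 40 characters: quick end-to-end material."""
    cfg = synthetic.SimulationConfig(n_taxa=8, n_characters=40, seed=11,
                                     n_groups=3)
    return synthetic.generate_bundle(cfg)


@pytest.fixture(scope="session")
def low_noise_wings(template):
    """50 wing shapes with tiny isotropic perturbations (sd 0.005)."""
    rng = np.random.default_rng(7)
    configs = [
        LandmarkConfiguration(f"w{i}", template.coords + rng.normal(0, 0.005,
                                                                    (template.k, 2)))
        for i in range(50)]
    return configs


@pytest.fixture(scope="session")
def aligned_low_noise(low_noise_wings):
    return gpa_align(low_noise_wings)


def random_shape(rng, k=8, scale=1.0):
    return LandmarkConfiguration(f"r{rng.integers(1e9)}",
                                 rng.normal(0, scale, (k, 2)))
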