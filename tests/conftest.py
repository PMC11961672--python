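import numpy as np
import pytest

from ptctools import simulate


@pytest.fixture(scope="session")
def small_stack():
    """A reusable mid-size image fixture with colocalized IF signal."""
    return simulate.gen_image_stack(shape=(8, 320, 320), n_nuclei=8,
                                    nucleus_radius=(18, 24), coloc_amplitude=0.25,
                                    seed=11)


@pytest.fixture(scope="session")
def genome_fixture():
    """A reusable null toy genome (no planted SNP/TF signal)."""
    return simulate.gen_genome_fixture(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
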