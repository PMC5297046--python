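import numpy as np
import pytest

from hybridhist.simulate import (EffectModel, GenomeModel, default_design,
                                 generate_counts, generate_genome)


@pytest.fixture(scope="session")
def genome():
    return generate_genome(GenomeModel(), seed=11)


@pytest.fixture(scope="session")
def simdata(genome):
    return generate_counts(genome, EffectModel(), default_design(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240911)
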