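import numpy as np
import pytest

from tumorspace import DynamicsParams, SamplingScheme, build_lattice, sample_cells, simulate


@pytest.fixture(scope="session")
def small_run():
    """A deterministic contact-process run on an 11x11 lattice."""
    graph = build_lattice((11, 11))
    params = DynamicsParams(alpha=0.4, beta=0.01, t_max=25.0)
    return simulate(graph, params, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_sample(small_run):
    samples = sample_cells(small_run, SamplingScheme(mode="random_n", n=8),
                           rng=np.random.default_rng(7))
    return small_run, samples
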