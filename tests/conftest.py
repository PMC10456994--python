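import numpy as np
import pytest

from certgeom import synth
from certgeom.geometry import classify_dimensions, decompose_recurrent


@pytest.fixture
def fig2():
    """Two-input toy problem with its feedforward decomposition."""
    spec, patterns = synth.fig2_toy()
    problem = decompose_recurrent(spec, patterns)[0]
    labels = classify_dimensions(problem.y_target, problem.n_synapses)
    return spec, patterns, problem, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_orthonormal_problem(seed, N=6, P=4, C=2):
    """Small random orthonormal configuration for property checks."""
    problem = synth.random_configuration(N, P, C, seed=seed)
    labels = classify_dimensions(problem.y_target, N)
    return problem, labels
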