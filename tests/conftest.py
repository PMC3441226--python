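import numpy as np
import pytest

from hgca import coexpression, fixtures


@pytest.fixture(scope="session")
def planted():
    """Expression fixture with two strong planted modules plus background.

    Returns (spec, matrix, module_map, correlation_matrix); module members
    have expected within-module r = 0.9 over 100 samples.
    """
    spec = fixtures.FixtureSpec(
        n_probes=50,
        n_samples=100,
        modules=(
            fixtures.ModuleSpec(5, 0.9, "PLANTED"),
            fixtures.ModuleSpec(6, 0.9, "SECOND"),
        ),
        seed=11,
    )
    matrix, module_map = fixtures.make_expression(spec)
    cm = coexpression.correlation_matrix(matrix)
    return spec, matrix, module_map, cm


@pytest.fixture
def rng():
    return np.random.default_rng(42)
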