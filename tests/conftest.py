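import numpy as np
import pytest

from morphogrowth.registration import register_pair
from morphogrowth.synthetic import ExpressionSpec, PhantomSpec, generate_expression, generate_phantom


@pytest.fixture(scope="session")
def phantom48():
    """Default-condition phantom pair on the standard 48-cubed grid."""
    return generate_phantom(PhantomSpec(n_weeks=2))


@pytest.fixture(scope="session")
def phantom32():
    """Smaller, faster phantom for unit-level checks."""
    return generate_phantom(PhantomSpec(grid_shape=(32, 32, 32), n_weeks=3, seed=1))


@pytest.fixture(scope="session")
def registered48(phantom48):
    """Week 0 -> 1 registration of the default phantom (shared: this is the
    expensive fixture).  Returns (series, displacement field, affine)."""
    disp, aff = register_pair(phantom48.volumes[1], phantom48.volumes[0])
    return phantom48, disp, aff


@pytest.fixture(scope="session")
def expression_small():
    spec = ExpressionSpec(n_genes=3000, planted_gene_count=8, seed=11)
    table, truth = generate_expression(spec)
    return spec, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
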