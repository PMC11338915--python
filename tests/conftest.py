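import numpy as np
import pytest

from lungctr.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Clean default phantom (512x512, thorax 400 px, heart 180 px) with truth."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom for fast oracle-equivalence checks."""
    spec = PhantomSpec(width=256, height=256, thorax_width=200, heart_width=90,
                       apex_y=40, base_y=216, diaphragm_arch=20, seed=2)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
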