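import numpy as np
import pytest

from biofusion.synthetic import generate_phenotypes


@pytest.fixture(scope="session")
def phenotypes5():
    """Five subject phenotypes shared by separability checks."""
    return generate_phenotypes(5, gender_ratio=0.4, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
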