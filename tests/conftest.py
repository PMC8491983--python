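import numpy as np
import pytest

from pdl1quant import ImageSimParams, QuantConfig, generate_ihc_pair


@pytest.fixture(scope="session")
def default_config():
    return QuantConfig()


@pytest.fixture(scope="session")
def clean_pair_f30():
    """A melanin-free pair with 30% PD-L1+ cells (shared; do not mutate)."""
    return generate_ihc_pair(ImageSimParams(pdl1_fraction=0.30, seed=11))


@pytest.fixture(scope="session")
def melanin_pair_f30():
    """Same layout as clean_pair_f30 plus 10% melanin on both slides."""
    return generate_ihc_pair(
        ImageSimParams(pdl1_fraction=0.30, melanin_area_fraction=0.10, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
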