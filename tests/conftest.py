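import numpy as np
import pytest

from cmost import LifeTable, NaturalHistoryParams
from cmost.params import AnchorCDF


@pytest.fixture(scope="session")
def life_table():
    return LifeTable.us_2008()


@pytest.fixture(scope="session")
def default_params():
    return NaturalHistoryParams()


@pytest.fixture(scope="session")
def calibrated13():
    from cmost import builtin_params
    return builtin_params(13)


@pytest.fixture
def unit_anchors():
    """Degenerate anchor CDFs mapping every quantile to multiplier 1."""
    flat = AnchorCDF((0.0, 1.0), (1.0, 1.0))
    return dict(individual_risk_anchors=flat,
                adenoma_risk_anchors_early=flat,
                adenoma_risk_anchors_advanced=flat)


@pytest.fixture
def no_lesion_params(default_params):
    """Parameters under which nobody ever develops a lesion."""
    return default_params.replace(a0=0.0,
                                  direct_cancer_risk=(0.0,) * 13)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
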