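import numpy as np
import pytest

from netmetareg import (
    ModelSpec,
    build_design,
    center_covariate,
    fit_gls,
    triangle_fixture,
)


@pytest.fixture
def triangle():
    """The deterministic 3-treatment fixture, centred at the mean covariate."""
    return center_covariate(triangle_fixture(), "mean")


@pytest.fixture
def triangle_raw():
    return triangle_fixture()


@pytest.fixture
def fe_design(triangle):
    """Fixed-effect, independent-interaction design on the centred triangle."""
    return build_design(triangle, ModelSpec(effects="fixed", interactions="independent"))


@pytest.fixture
def fe_fit(fe_design):
    return fit_gls(fe_design)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
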