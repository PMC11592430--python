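import numpy as np
import pytest

from derangetropy import make_distribution

#: The five analytic families at the parameter values used throughout.
FAMILY_PARAMS = {
    "uniform": (0.0, 1.0),
    "normal": (0.0, 1.0),
    "exponential": (1.0,),
    "semicircle": (-1.0, 1.0),
    "arcsin": (0.0, 1.0),
}


@pytest.fixture(scope="session", params=sorted(FAMILY_PARAMS))
def family_dist(request):
    """Each of the five analytic families, one at a time."""
    return make_distribution(request.param, FAMILY_PARAMS[request.param])


@pytest.fixture(scope="session")
def all_families():
    return {
        name: make_distribution(name, params)
        for name, params in FAMILY_PARAMS.items()
    }


@pytest.fixture(scope="session")
def unit_uniform():
    return make_distribution("uniform", (0.0, 1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240996)
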