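import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import numpy as np  # noqa: E402
from scipy.stats import hypergeom  # noqa: E402

from tetradmap import datasets  # noqa: E402


def enumeration_p(a, b, c, d):
    """Independent oracle: two-sided Fisher p by full hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (with a relative
    guard for floating-point ties).
    """
    n1, n2, m = a + b, c + d, a + c
    support = np.arange(max(0, m - n2), min(n1, m) + 1)
    pmf = hypergeom.pmf(support, n1 + n2, n1, m)
    observed = hypergeom.pmf(a, n1 + n2, n1, m)
    return float(pmf[pmf <= observed * (1 + 1e-10)].sum())


@pytest.fixture(scope="session")
def x_map():
    return datasets.X_MAP


@pytest.fixture(scope="session")
def third_map():
    return datasets.THIRD_MAP


@pytest.fixture(scope="session")
def x_control():
    return datasets.X_CONTROL


@pytest.fixture(scope="session")
def x_replacement():
    return datasets.X_REPLACEMENT


@pytest.fixture(scope="session")
def third_control():
    return datasets.THIRD_CONTROL


@pytest.fixture(scope="session")
def third_replacement():
    return datasets.THIRD_REPLACEMENT
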