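import numpy as np
import pytest

from tecelong import (
    SimulationParams,
    default_bin_scheme,
    default_template,
    make_landscape,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def scheme():
    return default_bin_scheme()


@pytest.fixture(scope="session")
def free_landscape(template):
    return make_landscape(template, "HTkA-free")


@pytest.fixture(scope="session")
def wt_landscape(template):
    return make_landscape(template, "WT")


@pytest.fixture()
def fast_params():
    """Quick barrier-free ensemble: fast release, moderate stepping."""
    return SimulationParams(k_step=0.5, k_release=10.0, n_molecules=5000, seed=101)


def chisquare_vs_oracle(counts: np.ndarray, probs: np.ndarray) -> float:
    """Goodness-of-fit p-value with low-expectation states pooled (>=5)."""
    from scipy.stats import chisquare

    n = counts.sum()
    expected = probs * n
    order = np.argsort(expected)[::-1]
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for i in order:
        acc_o += counts[i]
        acc_e += expected[i]
        if acc_e >= 5:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    pooled_obs = np.asarray(pooled_obs)
    pooled_exp = np.asarray(pooled_exp) * (n / np.sum(pooled_exp))
    return chisquare(pooled_obs, pooled_exp).pvalue
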