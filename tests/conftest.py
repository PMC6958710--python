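import numpy as np
import pytest

from redqueen import ModelParams, load_preset


@pytest.fixture(scope="session")
def fig1():
    """Two-genotype comparison preset (N_H=50, N_P=150 equilibrium)."""
    return load_preset("fig1")


@pytest.fixture(scope="session")
def fig3():
    """Population-size sweep preset (N_H=250, K=500)."""
    return load_preset("fig3")


@pytest.fixture(scope="session")
def fig4():
    """Five-genotype mutation-regime preset (N_H=300, N_P=900)."""
    return load_preset("fig4")


@pytest.fixture(scope="session")
def default_params():
    """Selection intensities and matching-allele payoffs used throughout."""
    return ModelParams(w_H=0.5, w_P=1.0, alpha=1.0, beta=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
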