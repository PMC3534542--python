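import warnings

import pytest

from pyrdetour import ConstraintSet, figure3_network, figure5_network

# fixture models intentionally contain none of the genome-scale cofactor ids;
# the resulting advisory warning is noise in this suite
warnings.filterwarnings(
    "ignore", message="no declared cofactor is present in the model")


@pytest.fixture(scope="session")
def fig3():
    return figure3_network()


@pytest.fixture(scope="session")
def fig5():
    return figure5_network()


@pytest.fixture()
def fig3_cset(fig3):
    return ConstraintSet.k_a(fig3, growth=0.1)


@pytest.fixture()
def fig5_cset(fig5):
    return ConstraintSet.k_a(fig5, growth=0.1)
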