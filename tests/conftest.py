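import numpy as np
import pytest

from rartest import TrialDesign, explicit_auxiliary


@pytest.fixture
def table1_design():
    """The worked-example design: t=2, n=11, n0=10, one burn-in per arm."""
    return TrialDesign(t=2, n=11, n0=10, burn_in=(1, 1))


@pytest.fixture
def table1_aux():
    return explicit_auxiliary("1221221121", t=2)


@pytest.fixture
def table1_actual():
    return np.array([1, 2, 2, 2, 1, 2, 2, 1, 2, 1, 2])


@pytest.fixture
def seq_design():
    """Fully sequential two-arm study design: 50 adaptive patients after a
    5-per-arm burn-in, 30 controls."""
    return TrialDesign(t=2, n=60, n0=30, burn_in=(5, 5))


@pytest.fixture
def block_design():
    """Small three-block two-arm design for block-weight tests."""
    return TrialDesign(
        t=2,
        n=34,
        n0=17,
        burn_in=(2, 2),
        block_sizes=(10, 10, 10),
        control_block_sizes=(5, 5, 5),
        control_burn_in=2,
    )
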