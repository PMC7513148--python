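import pytest

import trajent as tj

# The larger chains are solved once per session and shared: several tests
# interrogate the same fitted processes (extrema, duality, symmetry).


@pytest.fixture(scope="session")
def hawk_dove_30():
    """Hawk–Dove, N=30, Fermi beta=1, mu=1/30 (31 states)."""
    return tj.MoranModel.from_preset("hawkdove", 30, beta=1.0, mu=1 / 30).fit()


@pytest.fixture(scope="session")
def three_type_42():
    """Symmetric three-type game, N=42, beta=1, mu=1/42 (946 states)."""
    return tj.MoranModel.from_preset("threetype", 42, beta=1.0, mu=1 / 42).fit()


@pytest.fixture(scope="session")
def three_type_60():
    """Symmetric three-type game, N=60, beta=1, mu=1/60 (1891 states)."""
    return tj.MoranModel.from_preset("threetype", 60, beta=1.0, mu=1 / 60).fit()


@pytest.fixture(scope="session")
def rps_30():
    """Rock–paper–scissors, N=30, beta=1.5, mu=1/30 (496 states)."""
    return tj.MoranModel.from_preset("rps", 30, beta=1.5, mu=1 / 30).fit()


@pytest.fixture()
def two_state_chain():
    """The worked two-state chain [[0.9, 0.1], [0.5, 0.5]] whose stationary
    distribution (5/6, 1/6) solves the balance equation by hand."""
    import numpy as np

    return tj.FiniteMarkovProcess([0, 1], np.array([[0.9, 0.1], [0.5, 0.5]]))
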