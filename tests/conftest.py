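import numpy as np
import pytest

from qsabr import ReactantElectronicRecord, make_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """One paper-scale synthetic benchmark (72 reactions, 55/17 split)."""
    return make_benchmark("paper_like_linear", seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_reactant(rng, role, ident="r"):
    """A physically plausible random reactant record."""
    return ReactantElectronicRecord(
        id=ident,
        role=role,
        e_homo=float(rng.uniform(-0.45, -0.25)),
        e_lumo=float(rng.uniform(-0.10, 0.15)),
        dipole=float(rng.uniform(0.0, 6.0)),
    )
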