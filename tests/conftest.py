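import numpy as np
import pytest

from flashmap.core import Atom, AtomicModel, UnitCell


@pytest.fixture
def cell():
    return UnitCell(20.0, 24.0, 28.0)


def make_model(cell, n_atoms=5, seed=0, elements=("C", "N", "O"), b=(5.0, 20.0)):
    """Random small model for structure-factor oracles."""
    rng = np.random.default_rng(seed)
    atoms = [
        Atom(
            serial=i + 1, chain="A", resid=i + 1, resname="ALA", name="CA",
            element=str(rng.choice(list(elements))),
            frac=rng.uniform(0, 1, 3),
            occ=float(rng.uniform(0.5, 1.0)),
            b=float(rng.uniform(*b)),
        )
        for i in range(n_atoms)
    ]
    return AtomicModel(cell, atoms)


@pytest.fixture
def random_model(cell):
    return make_model(cell)
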