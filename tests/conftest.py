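import numpy as np
import pytest

from parmfit.ffio import (
    AtomRecord,
    BondParam,
    AngleParam,
    DihedralTerm,
    LJParam,
    ParameterSet,
    system_from_bonds,
)
from parmfit.mm_energy import Conformation
from parmfit.synthetic import make_toy_butane, make_fragment, FRAGMENT_NAMES


@pytest.fixture(scope="session")
def butane():
    return make_toy_butane()


@pytest.fixture(scope="session", params=FRAGMENT_NAMES)
def fragment(request):
    return make_fragment(request.param)


def atom(i, type_label="CT", charge=0.0, mass=12.011, name=None, element="C"):
    return AtomRecord(
        index=i + 1,
        name=name or f"A{i + 1}",
        type_label=type_label,
        charge=charge,
        mass=mass,
        element=element,
    )


@pytest.fixture
def four_atom_chain():
    """A bare 4-atom chain (3 bonds, 2 angles, 1 dihedral) in a gauche-like
    geometry, with a minimal self-consistent parameter set."""
    atoms = [atom(i) for i in range(4)]
    system = system_from_bonds(atoms, [(0, 1), (1, 2), (2, 3)])
    coords = np.array(
        [
            [0.0, 1.2, 0.3],
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [1.9, 1.1, 0.9],
        ]
    )
    params = ParameterSet()
    params.add_bond("CT", "CT", BondParam(250.0, 1.5))
    params.add_angle("CT", "CT", "CT", AngleParam(45.0, 111.0))
    params.add_dihedral_term(("X", "CT", "CT", "X"), DihedralTerm(0.2, 3, 0.0))
    params.add_lj("CT", LJParam(0.06, 2.0))
    return system, Conformation(coords), params
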