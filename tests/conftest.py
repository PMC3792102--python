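import numpy as np
import pytest

from tsadesign.synth import (
    ToyComplexSpec,
    generate_toy_complex,
    synthetic_rotamer_library,
)
from tsadesign.system import Atom, BondedTopology, MolecularSystem


def make_atom(i, **kwargs):
    defaults = dict(
        atom_id=i + 1, name=f"X{i + 1}", element="C", residue_id=1,
        residue_name="LIG", chain="A", molecule_tag="other",
        charge=0.0, lj_epsilon=0.0, lj_rmin_half=1.8,
        born_radius=1.5, sasa_coefficient=0.0, vdw_radius=1.7,
    )
    defaults.update(kwargs)
    return Atom(**defaults)


def diatomic(r, k_b=100.0, r0=1.5, **atom_kwargs):
    atoms = [make_atom(0, **atom_kwargs), make_atom(1, **atom_kwargs)]
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    topo = BondedTopology(bonds=[(0, 1, k_b, r0)])
    return MolecularSystem(atoms, coords, topo)


@pytest.fixture
def toy_pair():
    """Small complementary-charge substrate/TSA complexes plus restraints."""
    return generate_toy_complex(ToyComplexSpec(seed=7))


@pytest.fixture(scope="session")
def rotamer_library():
    return synthetic_rotamer_library()


@pytest.fixture
def random_cluster():
    """A seeded random charged atom cluster with a few bonded terms, smooth
    everywhere (sasa coefficients zero so the energy is differentiable)."""
    rng = np.random.default_rng(42)
    n = 6
    atoms = [
        make_atom(
            i,
            charge=float(rng.uniform(-0.4, 0.4)),
            lj_epsilon=0.2,
            lj_rmin_half=1.6,
            born_radius=float(rng.uniform(1.2, 2.2)),
        )
        for i in range(n)
    ]
    coords = rng.uniform(0.0, 6.0, size=(n, 3))
    # keep all pairs comfortably apart to avoid LJ blow-up in FD checks
    coords = coords * 1.4
    topo = BondedTopology(
        bonds=[(0, 1, 120.0, 2.0), (1, 2, 90.0, 2.2)],
        angles=[(0, 1, 2, 40.0, 1.9)],
        urey_bradley=[(0, 2, 25.0, 3.4)],
        dihedrals=[(0, 1, 2, 3, 4.0, 2, 0.5)],
        impropers=[(1, 0, 2, 3, 12.0, 0.4)],
    )
    return MolecularSystem(atoms, coords, topo)
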