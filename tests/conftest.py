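import numpy as np
import pytest

from surfads.core import Atom, MolecularSystem
from surfads import synthetic as syn


def single_atom_system(radius=0.17, center=(0.0, 0.0, 0.0)):
    atom = Atom(index=0, name="C1", element="C", residue_index=0,
                residue_name="UNK", radius=radius)
    return MolecularSystem([atom], np.array([center], dtype=float))


def pair_system(distance, radius=0.17):
    atoms = [Atom(index=i, name=f"C{i}", element="C", residue_index=0,
                  residue_name="UNK", radius=radius) for i in range(2)]
    pos = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return MolecularSystem(atoms, pos)


@pytest.fixture
def carbon_atom():
    return single_atom_system()


@pytest.fixture
def ala_leu_ala():
    return syn.make_toy_peptide("ALA LEU ALA")


@pytest.fixture
def mixed_peptide():
    return syn.make_toy_peptide("ALA LEU VAL GLY PHE SER")
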