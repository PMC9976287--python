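"""Shared fixtures: small molecules and scaffolds built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ligandshell.anchors import DEFAULT_GROUPS, apply_split, match_functional_groups
from ligandshell.fixtures import LatticeSpec, build_rocksalt_cube
from ligandshell.io import molecule_from_smiles
from ligandshell.molecule import Atom, Molecule


@pytest.fixture(scope="session")
def mpa():
    """Mercaptopropionic acid with explicit hydrogens and 3D coordinates."""
    return molecule_from_smiles("SCCC(=O)O", seed=11)


@pytest.fixture(scope="session")
def rocksalt_cube():
    return build_rocksalt_cube(LatticeSpec(lattice_constant=5.64, repeats=(2, 2, 2)))


@pytest.fixture(scope="session")
def octanoate():
    """n-octanoate candidate (carboxylate, split applied)."""
    proto = molecule_from_smiles("CCCCCCCC(=O)O", seed=11)
    cands = match_functional_groups(proto, DEFAULT_GROUPS)
    acid = next(c for c in cands if c.group.name == "carboxylic acid")
    return apply_split(acid)


def identity_optimizer(mol: Molecule) -> Molecule:
    """Optimizer stub honouring the relaxation contract without moving atoms;
    keeps graph-level tests independent of the force field."""
    return mol.copy()


@pytest.fixture
def cube_corner_anchors():
    """Unit-cube corner positions as an anchor set over a Cl8 molecule."""
    from ligandshell.surface import AnchorSet

    pts = np.array(
        [[i, j, k] for i in (0.0, 1.0) for j in (0.0, 1.0) for k in (0.0, 1.0)]
    )
    mol = Molecule(atoms=[Atom("Cl", tuple(p)) for p in pts])
    return mol, AnchorSet(tuple(range(8)), pts)


def random_branched_acid_smiles(rng: np.random.Generator) -> str:
    """A random small branched alkyl chain terminated by a carboxylic acid."""
    n_backbone = int(rng.integers(3, 7))
    chain = []
    for i in range(n_backbone):
        if i > 0 and rng.random() < 0.4:
            branch = "C" * int(rng.integers(1, 3))
            chain.append(f"C({branch})")
        else:
            chain.append("C")
    return "".join(chain) + "C(=O)O"
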