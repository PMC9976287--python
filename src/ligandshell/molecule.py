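"""Lightweight molecular container shared by every stage of the pipeline.

The container deliberately tolerates *dummy* element symbols (``"A"``,
``"B"``, ...) that mark scaffold anchoring sites and are not part of the
periodic table; such atoms carry zero mass and zero covalent radius and can
never be round-tripped through a cheminformatics toolkit.  Conversion to and
from RDKit is therefore restricted to molecules made of real elements
(organic ligands), while scaffolds with dummies stay in this representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "Bond",
    "is_known_element",
    "covalent_radius",
    "to_rdkit",
    "from_rdkit",
]

# fmt: off
_ELEMENTS = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra", "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
    "Es", "Fm", "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)
# fmt: on
_ELEMENT_SET = frozenset(_ELEMENTS)
_ATOMIC_NUMBER = {sym: i + 1 for i, sym in enumerate(_ELEMENTS)}


def is_known_element(symbol: str) -> bool:
    """True if ``symbol`` is a periodic-table element (case-sensitive)."""
    return symbol in _ELEMENT_SET


def atomic_number(symbol: str) -> int:
    """Atomic number of a real element, 0 for dummy symbols."""
    return _ATOMIC_NUMBER.get(symbol, 0)


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Å (RDKit values); 0.0 for dummy symbols."""
    if not is_known_element(symbol):
        return 0.0
    from rdkit import Chem

    return Chem.GetPeriodicTable().GetRcovalent(_ATOMIC_NUMBER[symbol])


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, Cartesian position (Å), formal charge.

    ``element`` may be any string; symbols absent from the periodic table are
    treated as dummy (anchor-marker) atoms.
    """

    element: str
    position: tuple[float, float, float]
    formal_charge: int = 0

    def __post_init__(self) -> None:
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3 or not all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def is_dummy(self) -> bool:
        return not is_known_element(self.element)


# (i, j, order) with i < j; stored once per bond.
Bond = tuple[int, int, float]


def _canonical_bond(i: int, j: int, order: float = 1.0) -> Bond:
    if i == j:
        raise ValueError(f"self-bond on atom {i}")
    a, b = (i, j) if i < j else (j, i)
    return (a, b, float(order))


@dataclass
class Molecule:
    """An ordered collection of atoms plus an undirected bond set."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: set[Bond] = field(default_factory=set)
    name: str = ""
    properties: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bonds = {_canonical_bond(i, j, o) for i, j, o in self.bonds}
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom (n={n})")

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of Cartesian coordinates in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def formal_charges(self) -> np.ndarray:
        return np.array([a.formal_charge for a in self.atoms], dtype=int)

    @property
    def net_formal_charge(self) -> int:
        return int(sum(a.formal_charge for a in self.atoms))

    def formula(self, heavy_only: bool = False) -> dict[str, int]:
        """Element → count map; optionally exclude hydrogens."""
        out: dict[str, int] = {}
        for a in self.atoms:
            if heavy_only and a.element == "H":
                continue
            out[a.element] = out.get(a.element, 0) + 1
        return out

    def neighbors(self, i: int) -> list[int]:
        """Indices bonded to atom ``i``, ascending."""
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def bond_order(self, i: int, j: int) -> float | None:
        a, b = (i, j) if i < j else (j, i)
        for x, y, o in self.bonds:
            if (x, y) == (a, b):
                return o
        return None

    # -- construction helpers ------------------------------------------------

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=list(self.atoms),
            bonds=set(self.bonds),
            name=self.name,
            properties=dict(self.properties),
        )

    def add_atom(self, atom: Atom) -> int:
        self.atoms.append(atom)
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: float = 1.0) -> None:
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bond ({i},{j}) references a missing atom (n={n})")
        self.bonds.add(_canonical_bond(i, j, order))

    def with_positions(self, positions: np.ndarray) -> "Molecule":
        """Copy with replaced coordinates; everything else preserved."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError(f"expected {(len(self.atoms), 3)} positions, got {positions.shape}")
        atoms = [replace(a, position=tuple(p)) for a, p in zip(self.atoms, positions)]
        return Molecule(atoms=atoms, bonds=set(self.bonds), name=self.name, properties=dict(self.properties))

    def subset(self, indices: Iterable[int]) -> "Molecule":
        """Sub-molecule of the given atoms, keeping only internal bonds.

        Atom order follows ``indices``; bonds are re-indexed accordingly.
        """
        idx = list(indices)
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate indices in subset")
        remap = {old: new for new, old in enumerate(idx)}
        atoms = [self.atoms[i] for i in idx]
        bonds = {
            _canonical_bond(remap[i], remap[j], o)
            for i, j, o in self.bonds
            if i in remap and j in remap
        }
        return Molecule(atoms=atoms, bonds=bonds, name=self.name, properties=dict(self.properties))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Apply the rigid motion x -> R x + t to all coordinates."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return self.with_positions(self.positions @ rotation.T + translation)


def merge(parts: Iterable[Molecule], name: str = "") -> tuple[Molecule, list[list[int]]]:
    """Concatenate molecules; returns the merged molecule and, per part, the
    list of merged-molecule indices its atoms were mapped to."""
    atoms: list[Atom] = []
    bonds: set[Bond] = set()
    maps: list[list[int]] = []
    for part in parts:
        offset = len(atoms)
        maps.append([offset + i for i in range(len(part.atoms))])
        atoms.extend(part.atoms)
        for i, j, o in part.bonds:
            bonds.add(_canonical_bond(i + offset, j + offset, o))
    return Molecule(atoms=atoms, bonds=bonds, name=name), maps


# -- RDKit interchange -------------------------------------------------------

_BOND_ORDER_TO_RDKIT = {1.0: "SINGLE", 2.0: "DOUBLE", 3.0: "TRIPLE", 1.5: "AROMATIC"}


def to_rdkit(mol: Molecule, sanitize: bool = True):
    """Convert to an RDKit Mol with a 3D conformer.

    Raises ``ValueError`` for molecules containing dummy atoms, which have no
    RDKit representation.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401  (registers conformer code)
    from rdkit.Geometry import Point3D

    for a in mol.atoms:
        if a.is_dummy:
            raise ValueError(f"cannot convert dummy element {a.element!r} to RDKit")
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for i, j, o in mol.bonds:
        bt = getattr(Chem.BondType, _BOND_ORDER_TO_RDKIT.get(o, "SINGLE"))
        rw.AddBond(int(i), int(j), bt)
    out = rw.GetMol()
    conf = Chem.Conformer(len(mol.atoms))
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, Point3D(*a.position))
    out.AddConformer(conf, assignId=True)
    if sanitize:
        Chem.SanitizeMol(out)
    return out


def from_rdkit(rdmol, name: str = "") -> Molecule:
    """Convert an RDKit Mol (with explicit Hs and a conformer) back."""
    conf = rdmol.GetConformer()
    atoms = []
    for i, ra in enumerate(rdmol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(Atom(ra.GetSymbol(), (p.x, p.y, p.z), ra.GetFormalCharge()))
    bonds: set[Bond] = set()
    for b in rdmol.GetBonds():
        order = b.GetBondTypeAsDouble()
        bonds.add(_canonical_bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return Molecule(atoms=atoms, bonds=bonds, name=name)
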