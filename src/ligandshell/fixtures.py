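"""Synthetic scaffolds: finite ionic lattice cuts used throughout the tests
and examples.

Two builders are provided.  ``build_rocksalt_cube`` tiles the conventional
8-atom rock-salt cell into a finite cube.  ``build_perovskite_cut`` produces
a (100)-terminated cut of a cubic double perovskite A2BB'X6 (elpasolite,
e.g. Cs2AgInCl6) with the A-cation/halide layer on every face.  The cut is
generated on the half-cell parity grid: with integer coordinates (i, j, k)
in units of a/2, B/B' sites have all-even coordinates (rock-salt ordered),
halides have exactly one odd coordinate, and A cations are all-odd; spanning
the odd range 1..2M-1 per axis yields an A/X-terminated cube with

    A = M^3,  B + B' = (M-1)^3,  X = 3 M (M-1)^2.

For M = 13 this is the ~6 nm A2197(BB')1728X5616 composition whose formal
charges (+1, +1, +3, -1) leave a surplus of +37 — balanced by deleting 37
surface A cations.  All cuts here are finite, non-periodic clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .molecule import Atom, Molecule

__all__ = [
    "LatticeSpec",
    "ROCKSALT_MOTIF",
    "build_rocksalt_cube",
    "build_perovskite_cut",
    "formal_charge_excess",
    "neutralize_by_cation_removal",
]

# conventional rock-salt cell: cation on the fcc lattice, anion offset by a/2
ROCKSALT_MOTIF: tuple[tuple[str, tuple[float, float, float], int], ...] = (
    ("Na", (0.0, 0.0, 0.0), 1),
    ("Na", (0.5, 0.5, 0.0), 1),
    ("Na", (0.5, 0.0, 0.5), 1),
    ("Na", (0.0, 0.5, 0.5), 1),
    ("Cl", (0.5, 0.0, 0.0), -1),
    ("Cl", (0.0, 0.5, 0.0), -1),
    ("Cl", (0.0, 0.0, 0.5), -1),
    ("Cl", (0.5, 0.5, 0.5), -1),
)


@dataclass(frozen=True)
class LatticeSpec:
    """Finite-cluster lattice recipe.

    ``lattice_constant`` is the conventional cubic cell edge in Å;
    ``repeats`` the number of cells (or, for perovskite cuts, A-cation
    planes) per axis; ``motif`` the basis as (element, fractional position,
    formal charge); ``termination`` which species to leave on (100) faces.
    """

    lattice_constant: float = 5.64
    repeats: tuple[int, int, int] = (2, 2, 2)
    motif: tuple[tuple[str, tuple[float, float, float], int], ...] = ROCKSALT_MOTIF
    termination: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.repeats):
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")
        for el, frac, _ in self.motif:
            if not all(0.0 <= f < 1.0 for f in frac):
                raise ValueError(f"motif position of {el} must lie in [0, 1), got {frac}")


def build_rocksalt_cube(spec: LatticeSpec = LatticeSpec()) -> Molecule:
    """Tile the motif over ``repeats`` conventional cells (no face sharing).

    The default two-ion rock-salt basis gives 8 × prod(repeats) atoms in a
    cube of edge ``lattice_constant × repeats``.
    """
    a = spec.lattice_constant
    rx, ry, rz = spec.repeats
    atoms = []
    for ix in range(rx):
        for iy in range(ry):
            for iz in range(rz):
                for el, (fx, fy, fz), q in spec.motif:
                    atoms.append(Atom(el, ((ix + fx) * a, (iy + fy) * a, (iz + fz) * a), q))
    name = f"rocksalt_{rx}x{ry}x{rz}"
    return Molecule(atoms=atoms, name=name)


#: double-perovskite species and formal charges: A(+1) 2 B(+1) B'(+3) X(-1) 6
_ELPASOLITE = {"A": ("Cs", 1), "B": ("Ag", 1), "Bp": ("In", 3), "X": ("Cl", -1)}


def build_perovskite_cut(
    repeats: int | tuple[int, int, int] = 5,
    lattice_constant: float = 10.5,
    species: dict[str, tuple[str, int]] | None = None,
) -> Molecule:
    """A-cation/halide-terminated (100) cut of a cubic double perovskite.

    ``repeats`` counts A-cation planes per axis (M); the cube edge, measured
    between the outermost A planes, is ``(M - 1) × lattice_constant / 2``.
    See the module docstring for the composition arithmetic; ``M = 13`` with
    the default 10.5 Å cell reproduces a ~6 nm nanocrystal.
    """
    if species is None:
        species = _ELPASOLITE
    if isinstance(repeats, int):
        reps = (repeats, repeats, repeats)
    else:
        reps = tuple(repeats)
    if any(m < 2 for m in reps):
        raise ValueError(f"need at least 2 A-planes per axis, got {reps}")
    half = lattice_constant / 2.0  # spacing of the parity grid, a0 = a/2
    atoms = []
    mx, my, mz = reps
    for i in range(1, 2 * mx):
        for j in range(1, 2 * my):
            for k in range(1, 2 * mz):
                odd = (i % 2) + (j % 2) + (k % 2)
                if odd == 3:
                    el, q = species["A"]
                elif odd == 1:
                    el, q = species["X"]
                elif odd == 0:
                    key = "B" if ((i + j + k) // 2) % 2 == 0 else "Bp"
                    el, q = species[key]
                else:  # two odd coordinates: vacant in the elpasolite net
                    continue
                # parity-grid unit is a quarter of the conventional cell edge
                atoms.append(Atom(el, (i * half / 2, j * half / 2, k * half / 2), q))
    name = f"perovskite_cut_M{mx}"
    return Molecule(atoms=atoms, name=name)


def formal_charge_excess(stoichiometry: dict[str, int], charges: dict[str, int]) -> int:
    """Net formal charge of a composition: Σ count × charge.

    Raises ``KeyError`` naming the element if a charge entry is missing.
    """
    total = 0
    for el, count in stoichiometry.items():
        if el not in charges:
            raise KeyError(f"no formal charge given for element {el!r}")
        total += count * charges[el]
    return total


def neutralize_by_cation_removal(
    scaffold: Molecule, element: str, mode: str = "uniform", seed: int = 42
) -> Molecule:
    """Delete surface ions of ``element`` until the net formal charge is zero.

    The number removed equals the scaffold's formal-charge surplus divided by
    the ion's charge; removal sites are distributed over the surface with the
    requested mode so the compensation does not pile up on one facet.
    """
    from .surface import AnchorSet, distance_matrix, select_anchor_subset, surface_atom_indices

    excess = scaffold.net_formal_charge
    if excess == 0:
        return scaffold.copy()
    ion_charge = None
    for a in scaffold.atoms:
        if a.element == element:
            ion_charge = a.formal_charge
            break
    if ion_charge is None:
        raise ValueError(f"no atoms of element {element!r} in scaffold")
    if ion_charge == 0 or excess % ion_charge != 0 or excess // ion_charge < 0:
        raise ValueError(
            f"cannot neutralize excess {excess:+d} by removing {element} ({ion_charge:+d}) ions"
        )
    n_remove = excess // ion_charge
    surf = surface_atom_indices(scaffold, element)
    if len(surf) < n_remove:
        raise ValueError(f"only {len(surf)} surface {element} ions, need to remove {n_remove}")
    anchors = AnchorSet(indices=tuple(surf), positions=scaffold.positions[surf])
    D = distance_matrix(anchors, mode="through_space")
    chosen = select_anchor_subset(anchors, D, n_remove, mode=mode, seed=seed)
    drop = set(chosen.indices)
    keep = [i for i in range(len(scaffold)) if i not in drop]
    out = scaffold.subset(keep)
    out.name = scaffold.name + "_neutral"
    return out
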