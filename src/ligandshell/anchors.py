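"""Ligand anchor discovery: functional-group matching and split edits.

A *proto-ligand* is any candidate molecule.  Matching each requested
functional group against it yields one :class:`LigandCandidate` per distinct
chemical occurrence — a proto-ligand with both a thiol and a carboxylic acid
therefore expands into two ligands with different anchor atoms.  The optional
*split* edit deprotonates the group (thiol → thiolate, acid → carboxylate) or
removes a user-specified leaving group (condensation, e.g. −OH off a
carboxyl) before attachment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .molecule import Atom, Molecule, to_rdkit

__all__ = [
    "FunctionalGroupSpec",
    "LigandCandidate",
    "DEFAULT_GROUPS",
    "builtin_group",
    "match_functional_groups",
    "apply_split",
    "enumerate_ligands",
]


@dataclass(frozen=True)
class FunctionalGroupSpec:
    """A substructure query defining a ligand anchoring group.

    ``pattern`` is a SMARTS (or plain SMILES, interpreted as a substructure
    query) string; ``anchor_idx`` indexes the anchoring atom *within the
    pattern*.  ``remove_idx`` lists pattern atoms deleted on attachment
    (their hydrogens go with them); when empty and ``split`` is true, a
    single proton on the anchor atom is removed instead (deprotonation).
    """

    pattern: str
    anchor_idx: int = 0
    remove_idx: tuple[int, ...] = ()
    split: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.anchor_idx in self.remove_idx:
            raise ValueError("anchor_idx cannot be part of the remove set")


# Patterns are written to pick out the chemically distinct site:
# the hydroxyl query excludes carboxylic OH so the two groups never
# both claim an acid's acidic oxygen.
DEFAULT_GROUPS: tuple[FunctionalGroupSpec, ...] = (
    FunctionalGroupSpec("[OX2H][CX4]", anchor_idx=0, split=True, name="hydroxyl"),
    FunctionalGroupSpec("[NX3;H2][#6]", anchor_idx=0, split=False, name="primary amine"),
    FunctionalGroupSpec("[NX4+;H3][#6]", anchor_idx=0, split=False, name="primary ammonium"),
    FunctionalGroupSpec("[CX3](=[OX1])[OX2H]", anchor_idx=2, split=True, name="carboxylic acid"),
    FunctionalGroupSpec("[SX2H]", anchor_idx=0, split=True, name="thiol"),
    FunctionalGroupSpec("[PX3;H0]", anchor_idx=0, split=False, name="phosphine"),
)


def builtin_group(name: str) -> FunctionalGroupSpec:
    for g in DEFAULT_GROUPS:
        if g.name == name:
            return g
    raise KeyError(f"no built-in functional group named {name!r}")


@dataclass
class LigandCandidate:
    """One (proto-ligand, functional-group occurrence) pair.

    ``edited`` is the molecule actually attached (after any split edit);
    ``edited_anchor`` is the anchor atom's index within it.  ``conformer``
    and ``ligand_vector`` are filled in by the conformer-bias stage.
    """

    proto: Molecule
    group: FunctionalGroupSpec
    match_atoms: tuple[int, ...]
    anchor_atom: int
    edited: Molecule
    edited_anchor: int
    net_charge_change: int = 0
    conformer: Molecule | None = None
    ligand_vector: object | None = None

    @property
    def label(self) -> str:
        g = self.group.name or self.group.pattern
        return f"{self.proto.name or 'ligand'}[{g}@{self.anchor_atom}]"


def _compile_query(pattern: str):
    """SMARTS first; plain SMILES promoted to a substructure query."""
    from rdkit import Chem

    patt = Chem.MolFromSmarts(pattern)
    if patt is None:
        smi = Chem.MolFromSmiles(pattern)
        if smi is None:
            raise ValueError(f"cannot parse functional-group pattern {pattern!r}")
        patt = Chem.AddHs(smi)
    return patt


def match_functional_groups(
    proto: Molecule, groups: list[FunctionalGroupSpec] | tuple[FunctionalGroupSpec, ...] = DEFAULT_GROUPS
) -> list[LigandCandidate]:
    """All distinct functional-group occurrences in a proto-ligand.

    Occurrences of the same group matching the same atom set (symmetry
    copies, e.g. swapped carboxyl oxygens) are deduplicated; distinct groups
    or distinct sites each yield their own candidate.  No edits are applied
    here — ``edited`` starts out identical to ``proto``.
    """
    rd = to_rdkit(proto)
    out: list[LigandCandidate] = []
    for group in groups:
        patt = _compile_query(group.pattern)
        if group.anchor_idx >= patt.GetNumAtoms():
            raise ValueError(
                f"anchor_idx {group.anchor_idx} out of range for pattern {group.pattern!r}"
            )
        seen: set[frozenset[int]] = set()
        for match in rd.GetSubstructMatches(patt, uniquify=True):
            key = frozenset(match)
            if key in seen:
                continue
            seen.add(key)
            anchor = match[group.anchor_idx]
            out.append(
                LigandCandidate(
                    proto=proto,
                    group=group,
                    match_atoms=tuple(match),
                    anchor_atom=anchor,
                    edited=proto.copy(),
                    edited_anchor=anchor,
                )
            )
    return out


class SplitError(ValueError):
    """The requested split/removal edit is impossible on this match."""


def apply_split(candidate: LigandCandidate) -> LigandCandidate:
    """Apply the group's split edit, returning a new candidate.

    Deprotonation (no ``remove_idx``): one hydrogen on the anchor atom is
    deleted and the anchor's formal charge is lowered by one.  Condensation
    (explicit ``remove_idx``): the designated pattern atoms, plus hydrogens
    riding on them, are deleted with no charge adjustment.  With
    ``split=False`` this is the identity.
    """
    group = candidate.group
    proto = candidate.proto
    if not group.split:
        return candidate

    removed: set[int] = set()
    charge_delta = 0
    if group.remove_idx:
        for k in group.remove_idx:
            if k >= len(candidate.match_atoms):
                raise SplitError(f"remove_idx {k} out of range for match {candidate.match_atoms}")
            removed.add(candidate.match_atoms[k])
        for i in set(removed):
            for j in proto.neighbors(i):
                if proto.atoms[j].element == "H":
                    removed.add(j)
        if candidate.anchor_atom in removed:
            raise SplitError("removal set swallowed the anchor atom")
    else:
        h_on_anchor = [j for j in proto.neighbors(candidate.anchor_atom) if proto.atoms[j].element == "H"]
        if not h_on_anchor:
            raise SplitError(
                f"split requested but anchor atom {candidate.anchor_atom} carries no hydrogen"
            )
        removed.add(h_on_anchor[0])
        charge_delta = -1

    keep = [i for i in range(len(proto)) if i not in removed]
    remap = {old: new for new, old in enumerate(keep)}
    edited = proto.subset(keep)
    if charge_delta:
        a = remap[candidate.anchor_atom]
        edited.atoms[a] = replace(edited.atoms[a], formal_charge=edited.atoms[a].formal_charge + charge_delta)
    return LigandCandidate(
        proto=proto,
        group=group,
        match_atoms=candidate.match_atoms,
        anchor_atom=candidate.anchor_atom,
        edited=edited,
        edited_anchor=remap[candidate.anchor_atom],
        net_charge_change=charge_delta,
    )


def enumerate_ligands(
    protos: list[Molecule],
    groups: list[FunctionalGroupSpec] | tuple[FunctionalGroupSpec, ...] = DEFAULT_GROUPS,
) -> list[LigandCandidate]:
    """Expand proto-ligands into candidates, proto order then match order.

    Duplicate proto-ligands yield duplicate candidates; no cross-proto
    deduplication is attempted.
    """
    out: list[LigandCandidate] = []
    for proto in protos:
        out.extend(match_functional_groups(proto, groups))
    return out
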