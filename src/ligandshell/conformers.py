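"""Biased conformer search: elongated, low-steric ligand geometries.

A ligand destined for a densely passivated surface should be as linear as
possible — its force-field global minimum often is not.  The search used
here biases toward elongation in five steps:

1. the (possibly branched) ligand is fragmented into linear heavy-atom
   chains, every broken bond capped with hydrogen; the chain construction
   keeps the anchor atom in the largest fragment;
2. every fragment is set anti-periplanar (backbone dihedrals 180°), except
   that a dihedral whose central bond contains the anchor atom is set
   syn-periplanar (0°);
3. fragments are reattached one by one: the caps are removed, the bond is
   reformed, and three rotamers about it (−120°/0°/+120°) are each relaxed
   with a force field (UFF by default);
4. the rotamer with the smallest weighted perpendicular spread about the
   ligand vector is retained;
5. repeat until all fragments are reattached.

Higher-level refinement (tight-binding, DFT, ...) is accommodated by the
optimizer contract — any callable mapping a molecule to a relaxed molecule —
but not bundled.

The *ligand vector* is the unit direction from the anchor atom minimizing
the weighted sum of the atoms' perpendicular distances to the line through
the anchor; it orients the ligand against the scaffold's surface normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np

from .geometry import rotation_between, unit
from .molecule import Atom, Molecule, covalent_radius, from_rdkit, to_rdkit

__all__ = [
    "FragmentPiece",
    "FragmentGraph",
    "Join",
    "LigandVector",
    "fragment_ligand",
    "set_periplanar",
    "perpendicular_score",
    "ligand_vector",
    "recombine_step",
    "biased_conformer_search",
    "uff_optimize",
]

Weight = Callable[[np.ndarray], np.ndarray] | None

_CAP_LENGTH = 1.09  # Å, C–H-like cap distance


def uff_optimize(mol: Molecule, max_iters: int = 400) -> Molecule:
    """Default optimizer: UFF relaxation; returns the input on failure."""
    try:
        rd = to_rdkit(mol)
        from rdkit import RDLogger
        from rdkit.Chem import AllChem

        RDLogger.DisableLog("rdApp.warning")  # UFF atom-typing chatter on ions
        try:
            AllChem.UFFOptimizeMolecule(rd, maxIters=max_iters)
        finally:
            RDLogger.EnableLog("rdApp.warning")
        out = from_rdkit(rd, name=mol.name)
        out.properties.update(mol.properties)
        return out
    except Exception:
        return mol.copy()


@dataclass(frozen=True)
class Join:
    """A bond broken during fragmentation, to be reformed on recombination.

    ``frag_a`` is always assembled before the join is processed; atoms are
    original-molecule indices.
    """

    frag_a: int
    atom_a: int
    frag_b: int
    atom_b: int
    order: float = 1.0


@dataclass
class FragmentPiece:
    """A capped fragment plus bookkeeping back to the original molecule.

    ``orig[i]`` is the original atom index of local atom ``i`` (None for cap
    hydrogens); ``caps`` maps each broken bond, keyed by
    (original atom in this piece, original atom on the far side), to the
    local index of the cap standing in for the far side.
    """

    mol: Molecule
    orig: list[int | None]
    caps: dict[tuple[int, int], int] = field(default_factory=dict)

    def local_of(self, orig_idx: int) -> int:
        return self.orig.index(orig_idx)


@dataclass
class FragmentGraph:
    pieces: list[FragmentPiece]
    joins: list[Join]
    anchor_fragment: int
    anchor_atom: int  # original-molecule index


def _heavy_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
    g.add_nodes_from(heavy)
    for i, j, o in mol.bonds:
        if mol.atoms[i].element != "H" and mol.atoms[j].element != "H":
            g.add_edge(i, j, order=o)
    return g


def _condense(g: nx.Graph) -> tuple[nx.Graph, dict]:
    """Contract atoms that must not be separated into supernodes.

    Only rotatable single bonds between non-terminal heavy atoms are worth
    cutting, so three groups are merged: ring systems (never cut), endpoints
    of multiple bonds (e.g. a carbonyl oxygen rides with its carbon), and
    terminal heavy atoms, which join their sole neighbour.  The condensed
    graph of a connected acyclic molecule is a tree whose nodes are
    frozensets of original heavy-atom indices.
    """
    # union-find over heavy atoms
    parent = {a: a for a in g.nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for cycle in nx.cycle_basis(g):
        for a in cycle[1:]:
            union(cycle[0], a)
    for i, j, data in g.edges(data=True):
        if data.get("order", 1.0) > 1.0:
            union(i, j)
    for a in list(g.nodes):
        if g.degree(a) == 1:
            union(a, next(iter(g.neighbors(a))))

    groups: dict[int, set[int]] = {}
    for a in g.nodes:
        groups.setdefault(find(a), set()).add(a)
    node_of: dict[int, frozenset[int]] = {}
    for members in groups.values():
        key = frozenset(members)
        for a in members:
            node_of[a] = key
    cg = nx.Graph()
    cg.add_nodes_from(set(node_of.values()))
    for i, j in g.edges:
        ni, nj = node_of[i], node_of[j]
        if ni != nj:
            cg.add_edge(ni, nj)
    return cg, node_of


def _deepest_path(tree: nx.Graph, root, blocked: set) -> list:
    """Heaviest (by member atom count) downward path from ``root``."""
    best = [root]
    for nb in tree.neighbors(root):
        if nb in blocked:
            continue
        sub = _deepest_path(tree, nb, blocked | {root})
        cand = [root] + sub
        if _path_weight(cand) > _path_weight(best):
            best = cand
    return best


def _path_weight(path) -> int:
    return sum(len(node) for node in path)


def fragment_ligand(lig: Molecule, anchor_atom: int) -> FragmentGraph:
    """Decompose a ligand into capped linear fragments (step 1).

    The anchor fragment is the heaviest chain through the anchor atom; the
    remaining branches are peeled off recursively as their own chains.  Only
    rotatable single bonds between non-terminal atoms are ever broken: ring
    systems, multiple-bond partners (a carbonyl O stays with its C) and
    terminal heavy atoms ride along inside their fragment.  Hydrogens stay
    with their heavy atom; every broken bond gets a hydrogen cap on both
    sides.
    """
    g_full = nx.Graph()
    g_full.add_nodes_from(range(len(lig)))
    g_full.add_edges_from((i, j) for i, j, _ in lig.bonds)
    if len(lig) and not nx.is_connected(g_full):
        raise ValueError("ligand must be a single connected molecule")
    if lig.atoms[anchor_atom].element == "H":
        raise ValueError("anchor atom cannot be a hydrogen")

    g = _heavy_graph(lig)
    tree, node_of = _condense(g)
    anchor_node = node_of[anchor_atom]

    # heaviest path through the anchor node: root two deepest branches there
    best_path = [anchor_node]
    branches = []
    for nb in tree.neighbors(anchor_node):
        branches.append(_deepest_path(tree, nb, {anchor_node}))
    branches.sort(key=_path_weight, reverse=True)
    if len(branches) >= 2:
        best_path = list(reversed(branches[0])) + [anchor_node] + branches[1]
    elif branches:
        best_path = [anchor_node] + branches[0]

    fragments_nodes: list[list] = []
    joins_nodes: list[tuple[int, frozenset, frozenset]] = []  # (parent frag, parent node, child root)
    assigned: set = set()

    def claim(path_nodes: list, frag_idx: int) -> None:
        assigned.update(path_nodes)
        fragments_nodes.append(path_nodes)
        path_set = set(path_nodes)
        for node in path_nodes:
            for nb in tree.neighbors(node):
                if nb in assigned or nb in path_set:
                    continue
                sub = _deepest_path(tree, nb, assigned | path_set)
                joins_nodes.append((frag_idx, node, nb))
                claim(sub, len(fragments_nodes))

    claim(best_path, 0)

    node_frag = {}
    for fi, nodes in enumerate(fragments_nodes):
        for node in nodes:
            node_frag[node] = fi

    # resolve node-level joins to atom-level bonds
    joins: list[Join] = []
    for fa, node_a, node_b in joins_nodes:
        fb = node_frag[node_b]
        bond = None
        for i in node_a:
            for j in g.neighbors(i):
                if j in node_b:
                    bond = (i, j, g.edges[i, j].get("order", 1.0))
        if bond is None:
            raise AssertionError("condensed join without an underlying bond")
        joins.append(Join(frag_a=fa, atom_a=bond[0], frag_b=fb, atom_b=bond[1], order=bond[2]))

    cut_bonds = {frozenset((j.atom_a, j.atom_b)) for j in joins}
    pos = lig.positions

    pieces: list[FragmentPiece] = []
    for nodes in fragments_nodes:
        heavy_atoms = sorted(a for node in nodes for a in node)
        atom_set = set(heavy_atoms)
        hydrogens = sorted(
            j
            for i in heavy_atoms
            for j in lig.neighbors(i)
            if lig.atoms[j].element == "H" and j not in atom_set
        )
        local_atoms = heavy_atoms + hydrogens
        remap = {oi: li for li, oi in enumerate(local_atoms)}
        atoms = [lig.atoms[i] for i in local_atoms]
        bonds = set()
        for i, j, o in lig.bonds:
            if i in remap and j in remap and frozenset((i, j)) not in cut_bonds:
                a, b = remap[i], remap[j]
                bonds.add((min(a, b), max(a, b), o))
        orig: list[int | None] = list(local_atoms)
        caps: dict[tuple[int, int], int] = {}
        for jn in joins:
            for here, there in ((jn.atom_a, jn.atom_b), (jn.atom_b, jn.atom_a)):
                if here in remap and there not in remap:
                    direction = unit(pos[there] - pos[here])
                    cap_pos = pos[here] + direction * _CAP_LENGTH
                    atoms.append(Atom("H", tuple(cap_pos)))
                    cap_local = len(atoms) - 1
                    bonds.add((min(remap[here], cap_local), max(remap[here], cap_local), 1.0))
                    orig.append(None)
                    caps[(here, there)] = cap_local
        pieces.append(FragmentPiece(mol=Molecule(atoms=atoms, bonds=bonds, name=lig.name), orig=orig, caps=caps))

    return FragmentGraph(pieces=pieces, joins=joins, anchor_fragment=0, anchor_atom=anchor_atom)


def _backbone_path(mol: Molecule) -> list[int]:
    """Heavy-atom path of a chain fragment (longest heavy path)."""
    g = _heavy_graph(mol)
    if g.number_of_nodes() < 4:
        return sorted(g.nodes)
    ends = [n for n in g.nodes if g.degree(n) <= 1]
    best: list[int] = []
    for i, a in enumerate(ends):
        lengths = nx.single_source_shortest_path(g, a)
        for b, path in lengths.items():
            if len(path) > len(best):
                best = path
    return best


def set_periplanar(frag: Molecule, anchor_atom: int | None = None) -> Molecule:
    """Set every backbone dihedral to 180° (0° when the central bond contains
    the anchor atom); bond lengths and angles are untouched.

    Fragments too short for a proper dihedral are returned unchanged.  Ring
    bonds, if any survived fragmentation inside a ring system, are skipped.
    """
    path = _backbone_path(frag)
    if len(path) < 4:
        return frag.copy()
    rd = to_rdkit(frag, sanitize=False)
    from rdkit.Chem import rdmolops, rdMolTransforms

    rdmolops.FastFindRings(rd)
    conf = rd.GetConformer()
    for k in range(len(path) - 3):
        p0, p1, p2, p3 = path[k : k + 4]
        bond = rd.GetBondBetweenAtoms(p1, p2)
        if bond is None or bond.IsInRing():
            continue
        target = 0.0 if anchor_atom in (p1, p2) else 180.0
        rdMolTransforms.SetDihedralDeg(conf, p0, p1, p2, p3, target)
    out = from_rdkit(rd, name=frag.name)
    # from_rdkit loses nothing here, but re-assert the original bond orders
    out.bonds = set(frag.bonds)
    out.properties.update(frag.properties)
    return out


def perpendicular_score(
    lig: Molecule, anchor_atom: int, v: np.ndarray, weight: Weight = None
) -> float:
    """Weighted sum of the atoms' perpendicular distances (Å) to the line
    through the anchor atom with direction ``v`` (a unit vector)."""
    v = np.asarray(v, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("direction vector must be nonzero")
    v = v / nv
    r = lig.positions - lig.positions[anchor_atom]
    perp = r - np.outer(r @ v, v)
    d = np.linalg.norm(perp, axis=1)
    if weight is not None:
        d = d * weight(np.linalg.norm(r, axis=1))
    return float(d.sum())


@dataclass(frozen=True)
class LigandVector:
    """Optimized ligand direction: unit vector, its origin (anchor position,
    Å), and the residual perpendicular-spread score (Å)."""

    v: np.ndarray
    origin: np.ndarray
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


def _angles_to_vec(theta: float, phi: float) -> np.ndarray:
    return np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])


def ligand_vector(
    lig: Molecule,
    anchor_atom: int,
    weight: Weight = None,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> LigandVector:
    """Self-consistent ligand vector.

    The initial guess points from the anchor atom to the mean position of
    all atoms; the direction is then refined by local minimization of the
    perpendicular-spread score and iterated until successive directions
    differ by less than ``tol`` radians.  The returned score never exceeds
    the initial guess's.
    """
    from scipy.optimize import minimize

    if len(lig) < 2:
        raise ValueError("ligand vector needs at least two atoms")
    pos = lig.positions
    origin = pos[anchor_atom]
    guess = pos.mean(axis=0) - origin
    if np.linalg.norm(guess) < 1e-12:
        raise ValueError("atoms coincide with the anchor; ligand direction undefined")
    v = unit(guess)
    best_score = perpendicular_score(lig, anchor_atom, v, weight)

    def objective(x):
        return perpendicular_score(lig, anchor_atom, _angles_to_vec(*x), weight)

    for _ in range(max_iter):
        theta = float(np.arccos(np.clip(v[2], -1, 1)))
        phi = float(np.arctan2(v[1], v[0]))
        res = minimize(objective, x0=[theta, phi], method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-10})
        v_new = _angles_to_vec(*res.x)
        if float(res.fun) > best_score:
            break
        best_score = float(res.fun)
        delta = float(np.arccos(np.clip(abs(np.dot(v, v_new)), -1, 1)))
        v = v_new
        if delta < tol:
            break
    if np.dot(v, guess) < 0:
        v = -v
    return LigandVector(v=v, origin=origin, score=best_score)


def recombine_step(
    state: FragmentPiece,
    frag: FragmentPiece,
    join: Join,
    optimizer: Callable[[Molecule], Molecule] = uff_optimize,
    anchor_atom: int | None = None,
    weight: Weight = None,
) -> FragmentPiece:
    """Reattach one fragment (steps 3–4).

    Both caps are removed, the bond is reformed at the sum of covalent radii,
    and three rotamers about the new bond (offsets −120°, 0°, +120° from the
    incoming dihedral) are relaxed; the one minimizing the perpendicular
    spread about the current ligand vector is kept.
    """
    cap_a = state.caps.get((join.atom_a, join.atom_b))
    cap_b = frag.caps.get((join.atom_b, join.atom_a))
    if cap_a is None or cap_b is None:
        raise ValueError(f"join {join} does not match the pieces' cap bookkeeping")
    a_local = state.local_of(join.atom_a)
    b_local = frag.local_of(join.atom_b)
    pos_state = state.mol.positions
    pos_frag = frag.mol.positions

    direction = unit(pos_state[cap_a] - pos_state[a_local])
    bond_len = covalent_radius(state.mol.atoms[a_local].element) + covalent_radius(
        frag.mol.atoms[b_local].element
    )
    u_b = unit(pos_frag[cap_b] - pos_frag[b_local])
    R = rotation_between(u_b, -direction)
    target = pos_state[a_local] + direction * bond_len
    moved = frag.mol.with_positions((pos_frag - pos_frag[b_local]) @ R.T + target)

    # merge, dropping both caps
    keep_a = [i for i in range(len(state.mol)) if i != cap_a]
    keep_b = [i for i in range(len(frag.mol)) if i != cap_b]
    part_a = state.mol.subset(keep_a)
    part_b = moved.subset(keep_b)
    remap_a = {old: new for new, old in enumerate(keep_a)}
    remap_b = {old: len(keep_a) + new for new, old in enumerate(keep_b)}
    merged = Molecule(
        atoms=part_a.atoms + part_b.atoms,
        bonds=set(),
        name=state.mol.name,
        properties=dict(state.mol.properties),
    )
    for i, j, o in part_a.bonds:
        merged.add_bond(i, j, o)
    for i, j, o in part_b.bonds:
        merged.add_bond(i + len(keep_a), j + len(keep_a), o)
    na, nb = remap_a[a_local], remap_b[b_local]
    merged.add_bond(na, nb, join.order)

    orig = [state.orig[i] for i in keep_a] + [frag.orig[i] for i in keep_b]
    caps: dict[tuple[int, int], int] = {}
    for key, ci in state.caps.items():
        if ci != cap_a:
            caps[key] = remap_a[ci]
    for key, ci in frag.caps.items():
        if ci != cap_b:
            caps[key] = remap_b[ci]

    anchor_local = orig.index(anchor_atom) if anchor_atom is not None else orig.index(join.atom_a)

    rotamers = _rotamers_about(merged, na, nb)
    best: tuple[float, int, Molecule] | None = None
    errors = []
    for k, rot in enumerate(rotamers):
        try:
            relaxed = optimizer(rot)
            lv = ligand_vector(relaxed, anchor_local, weight)
            score = lv.score
        except Exception as exc:  # pragma: no cover - optimizer failure path
            errors.append(f"rotamer {k}: {exc}")
            continue
        if best is None or score < best[0] - 1e-12:
            best = (score, k, relaxed)
    if best is None:
        raise RuntimeError("all rotamers failed to relax: " + "; ".join(errors))
    return FragmentPiece(mol=best[2], orig=orig, caps=caps)


def _rotamers_about(mol: Molecule, a: int, b: int) -> list[Molecule]:
    """Three poses offset −120°/0°/+120° about bond a–b (or one, if either
    end lacks a heavy reference neighbour)."""
    heavy_nb_a = [i for i in mol.neighbors(a) if mol.atoms[i].element != "H" and i != b]
    heavy_nb_b = [i for i in mol.neighbors(b) if mol.atoms[i].element != "H" and i != a]
    if not heavy_nb_a or not heavy_nb_b:
        return [mol.copy()]
    p0, p3 = heavy_nb_a[0], heavy_nb_b[0]
    rd = to_rdkit(mol, sanitize=False)
    from rdkit.Chem import rdmolops, rdMolTransforms

    rdmolops.FastFindRings(rd)
    bond = rd.GetBondBetweenAtoms(a, b)
    if bond is None or bond.IsInRing():
        return [mol.copy()]
    conf = rd.GetConformer()
    base = rdMolTransforms.GetDihedralDeg(conf, p0, a, b, p3)
    out = []
    for off in (-120.0, 0.0, 120.0):
        rd_k = to_rdkit(mol, sanitize=False)
        rdmolops.FastFindRings(rd_k)
        rdMolTransforms.SetDihedralDeg(rd_k.GetConformer(), p0, a, b, p3, base + off)
        m = from_rdkit(rd_k, name=mol.name)
        m.bonds = set(mol.bonds)
        m.properties.update(mol.properties)
        out.append(m)
    return out


def biased_conformer_search(
    candidate,
    optimizer: Callable[[Molecule], Molecule] = uff_optimize,
    weight: Weight = None,
) -> Molecule:
    """Run the full fragmentation/recombination search on a ligand candidate.

    Returns the elongated conformer with atoms in the same order as
    ``candidate.edited`` (so ``candidate.edited_anchor`` stays valid).  The
    chemical graph is preserved exactly.
    """
    mol = candidate.edited
    anchor = candidate.edited_anchor
    if len(mol) == 0:
        raise ValueError("empty ligand")
    fg = fragment_ligand(mol, anchor)

    prepared: list[FragmentPiece] = []
    for piece in fg.pieces:
        local_anchor = piece.orig.index(anchor) if anchor in piece.orig else None
        shaped = set_periplanar(piece.mol, local_anchor)
        prepared.append(FragmentPiece(mol=shaped, orig=list(piece.orig), caps=dict(piece.caps)))

    states: dict[int, FragmentPiece] = {i: p for i, p in enumerate(prepared)}
    merged_into: dict[int, int] = {i: i for i in states}  # fragment -> current state key

    def root(i: int) -> int:
        while merged_into[i] != i:
            i = merged_into[i]
        return i

    state_key = root(fg.anchor_fragment)
    for join in fg.joins:
        ra, rb = root(join.frag_a), root(join.frag_b)
        new_piece = recombine_step(states[ra], states[rb], join, optimizer, fg.anchor_atom, weight)
        states[ra] = new_piece
        merged_into[rb] = ra
    final = states[root(fg.anchor_fragment)]

    if len(fg.joins) == 0:
        final = FragmentPiece(mol=optimizer(final.mol), orig=final.orig, caps=final.caps)

    # restore original atom order
    order = sorted(range(len(final.mol)), key=lambda i: final.orig[i])
    if any(o is None for o in final.orig):
        raise AssertionError("caps left over after recombination")
    out = final.mol.subset(order)
    out.name = mol.name
    out.properties.update(mol.properties)
    return out
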