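"""Rigid ligand attachment and assembly bookkeeping.

Each ligand is rigidly moved so its ligand vector lies along the outward
core vector of its site and its anchor atom sits exactly on the (removed)
dummy atom's position; it is then spun about that axis to the sampled
azimuth maximizing the minimum distance to all previously placed ligands.
Inter-ligand contacts closer than 1.4 Å are reported as warnings — a signal
that the assembly wants a follow-up geometry optimization, not a failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .anchors import LigandCandidate
from .conformers import LigandVector, ligand_vector
from .geometry import rotation_about_axis, rotation_between, unit
from .molecule import Molecule
from .surface import AnchorSet

__all__ = [
    "PlacedLigand",
    "AssemblyReport",
    "align_ligand",
    "azimuthal_optimize",
    "detect_clashes",
    "attach_all",
    "CLASH_THRESHOLD",
]

#: inter-ligand contact distance (Å) below which a warning is raised
CLASH_THRESHOLD = 1.4


@dataclass
class PlacedLigand:
    ligand: Molecule  # final pose
    site_index: int  # scaffold atom index the ligand replaced
    core_vector: np.ndarray
    azimuth: float  # radians


@dataclass
class AssemblyReport:
    structure: Molecule
    placements: list[PlacedLigand]
    ligand_atom_groups: list[list[int]]  # per ligand, atom indices in structure
    clash_pairs: list[tuple[int, int, float]]
    warnings: list[str]
    net_formal_charge: int


def align_ligand(
    lig: Molecule,
    lv: LigandVector,
    site: np.ndarray,
    cv: np.ndarray,
    reference: np.ndarray | None = None,
) -> Molecule:
    """Rigidly move ``lig`` so its ligand vector is parallel to the core
    vector ``cv`` and its anchor atom lands on ``site``.

    Without ``reference`` the azimuth about ``cv`` is the minimal-rotation
    one, which depends on the lab frame.  Passing a scaffold-derived
    ``reference`` direction canonicalizes it — the ligand's widest
    perpendicular lobe is turned toward the reference — making the pose
    equivariant under rigid motions of the scaffold.
    """
    cv = unit(cv)
    site = np.asarray(site, dtype=float)
    R = rotation_between(lv.v, cv)
    pos = (lig.positions - lv.origin) @ R.T + site
    if reference is not None:
        ref_perp = np.asarray(reference, dtype=float)
        ref_perp = ref_perp - np.dot(ref_perp, cv) * cv
        rel = pos - site
        perp = rel - np.outer(rel @ cv, cv)
        norms = np.linalg.norm(perp, axis=1)
        k = int(np.argmax(np.round(norms, 9)))  # widest lobe, ties to low index
        if np.linalg.norm(ref_perp) > 1e-8 and norms[k] > 1e-8:
            u = perp[k] / norms[k]
            w = ref_perp / np.linalg.norm(ref_perp)
            angle = float(np.arctan2(np.dot(np.cross(u, w), cv), np.dot(u, w)))
            pos = (pos - site) @ rotation_about_axis(cv, angle).T + site
    return lig.with_positions(pos)


def azimuthal_optimize(
    placed: Molecule,
    cv: np.ndarray,
    site: np.ndarray,
    neighbors: list[Molecule] | np.ndarray,
    n_samples: int = 24,
) -> tuple[Molecule, float]:
    """Spin ``placed`` about the core-vector axis to the pose, out of
    ``n_samples`` evenly spaced ones, maximizing its minimum interatomic
    distance to the neighbour atoms.  No neighbours (or a single sample)
    leaves the pose unchanged at azimuth 0."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if isinstance(neighbors, np.ndarray):
        nb_pos = neighbors
    else:
        nb_pos = (
            np.vstack([m.positions for m in neighbors]) if neighbors else np.zeros((0, 3))
        )
    if nb_pos.shape[0] == 0 or n_samples == 1:
        return placed.copy(), 0.0
    cv = unit(cv)
    site = np.asarray(site, dtype=float)
    rel = placed.positions - site
    tree = cKDTree(nb_pos)
    best_angle = 0.0
    best_min = -np.inf
    best_pos = placed.positions
    for k in range(n_samples):
        angle = 2.0 * np.pi * k / n_samples
        R = rotation_about_axis(cv, angle)
        pos = rel @ R.T + site
        dmin = tree.query(pos, k=1)[0].min()
        if dmin > best_min + 1e-12:
            best_min = dmin
            best_angle = angle
            best_pos = pos
    return placed.with_positions(best_pos), float(best_angle)


def detect_clashes(
    structure: Molecule, ligand_atom_groups: list[list[int]], threshold: float = CLASH_THRESHOLD
) -> list[tuple[int, int, float]]:
    """All atom pairs from *different* ligand groups closer than
    ``threshold`` Å, as (i, j, distance) with i < j."""
    group_of = {}
    for gi, group in enumerate(ligand_atom_groups):
        for i in group:
            if i in group_of:
                raise ValueError(f"atom {i} appears in two ligand groups")
            group_of[i] = gi
    idx = sorted(group_of)
    if not idx:
        return []
    pos = structure.positions[idx]
    tree = cKDTree(pos)
    out = []
    for a, b in tree.query_pairs(threshold):
        i, j = idx[a], idx[b]
        if group_of[i] != group_of[j]:
            d = float(np.linalg.norm(structure.positions[i] - structure.positions[j]))
            out.append((min(i, j), max(i, j), d))
    return sorted(out)


def attach_all(
    scaffold: Molecule,
    anchors: AnchorSet,
    core_vecs: np.ndarray,
    assignments: dict[int, LigandCandidate],
    n_azimuth: int = 24,
    clash_threshold: float = CLASH_THRESHOLD,
    radial_offset: float = 0.0,
    bond_to_scaffold: bool = False,
) -> AssemblyReport:
    """Attach a ligand to every assigned anchor site and merge.

    ``assignments`` maps scaffold anchor atom indices (a subset of
    ``anchors.indices``) to ligand candidates carrying an optimized
    conformer.  Sites are processed in ascending index order; each dummy is
    deleted, the ligand aligned to the site's core vector (optionally
    displaced ``radial_offset`` Å outward), then azimuthally packed against
    all previously placed ligands.  With ``bond_to_scaffold`` (covalent
    grafting) a bond is written from the dummy's scaffold neighbour to the
    ligand anchor atom.
    """
    if not assignments:
        raise ValueError("empty site -> ligand assignment")
    core_vecs = np.asarray(core_vecs, dtype=float)
    if core_vecs.shape != (len(anchors), 3):
        raise ValueError(f"need one core vector per anchor, got {core_vecs.shape}")
    site_to_row = {idx: row for row, idx in enumerate(anchors.indices)}
    for site in assignments:
        if site not in site_to_row:
            raise KeyError(f"assignment references atom {site}, which is not an anchor")

    sites = sorted(assignments)
    dummies = set(sites)
    keep = [i for i in range(len(scaffold)) if i not in dummies]
    base = scaffold.subset(keep)
    remap = {old: new for new, old in enumerate(keep)}

    warnings: list[str] = []
    placements: list[PlacedLigand] = []
    placed_atoms: list[np.ndarray] = []

    atoms = list(base.atoms)
    bonds = {(i, j, o) for i, j, o in base.bonds}
    groups: list[list[int]] = []

    for site in sites:
        cand = assignments[site]
        conf = cand.conformer if cand.conformer is not None else cand.edited
        lv = cand.ligand_vector
        if lv is None:
            lv = ligand_vector(conf, cand.edited_anchor)
        cv = core_vecs[site_to_row[site]]
        site_pos = np.asarray(scaffold.atoms[site].position) + radial_offset * unit(cv)
        # scaffold-derived azimuth reference: direction to the nearest other
        # anchor keeps the whole construction rigid-motion equivariant
        reference = None
        if len(anchors) > 1:
            rel = anchors.positions - np.asarray(scaffold.atoms[site].position)
            dist = np.linalg.norm(rel, axis=1)
            dist[site_to_row[site]] = np.inf
            reference = rel[int(np.argmin(np.round(dist, 9)))]
        aligned = align_ligand(conf, lv, site_pos, cv, reference=reference)
        nb = np.vstack(placed_atoms) if placed_atoms else np.zeros((0, 3))
        posed, azimuth = azimuthal_optimize(aligned, cv, site_pos, nb, n_azimuth)
        placements.append(PlacedLigand(posed, site, cv.copy(), azimuth))
        placed_atoms.append(posed.positions)

        offset = len(atoms)
        groups.append(list(range(offset, offset + len(posed))))
        atoms.extend(posed.atoms)
        for i, j, o in posed.bonds:
            bonds.add((i + offset, j + offset, o))
        if bond_to_scaffold:
            nbrs = [n for n in scaffold.neighbors(site) if n not in dummies]
            if len(nbrs) == 1:
                bonds.add(tuple(sorted((remap[nbrs[0]], offset + cand.edited_anchor))) + (1.0,))
            else:
                warnings.append(
                    f"site {site}: cannot write scaffold bond ({len(nbrs)} non-dummy neighbours)"
                )

    structure = Molecule(atoms=atoms, bonds=bonds, name=scaffold.name + "_passivated")
    clashes = detect_clashes(structure, groups, clash_threshold)
    for i, j, d in clashes:
        warnings.append(f"inter-ligand contact {i}-{j} at {d:.2f} Å (< {clash_threshold} Å)")
    return AssemblyReport(
        structure=structure,
        placements=placements,
        ligand_atom_groups=groups,
        clash_pairs=clashes,
        warnings=warnings,
        net_formal_charge=structure.net_formal_charge,
    )
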