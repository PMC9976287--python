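"""Anchor detection, hull surface model, distances, and greedy distribution."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from ligandshell.fixtures import LatticeSpec, build_rocksalt_cube
from ligandshell.molecule import Atom, Molecule
from ligandshell.surface import (
    AnchorSet,
    DegenerateSurfaceError,
    build_surface_model,
    core_vectors,
    distance_matrix,
    find_anchors,
    replace_surface,
    select_anchor_subset,
    surface_atom_indices,
)


def greedy_oracle(D: np.ndarray, k: int, mode: str) -> list[int]:
    """Independent step-by-step evaluation of the selection recurrence with
    plain Python loops: crowding of j = sum of exp(-d) over the reference
    set; uniform minimizes, cluster maximizes; ties to the lowest index."""
    n = D.shape[0]
    sign = 1.0 if mode == "cluster" else -1.0

    def crowding(j, ref):
        return sum(math.exp(-D[j, a]) for a in ref if a != j)

    first = max(range(n), key=lambda j: (sign * crowding(j, range(n)), -j))
    picked = [first]
    while len(picked) < k:
        cands = [j for j in range(n) if j not in picked]
        nxt = max(cands, key=lambda j: (sign * crowding(j, picked), -j))
        picked.append(nxt)
    return picked


# ---------------------------------------------------------------- anchors


def test_find_anchors_by_symbol(rocksalt_cube):
    anchors = find_anchors(rocksalt_cube, "Cl")
    expected = [i for i, a in enumerate(rocksalt_cube.atoms) if a.element == "Cl"]
    assert list(anchors.indices) == expected


def test_find_anchors_by_indices(rocksalt_cube):
    anchors = find_anchors(rocksalt_cube, [7, 0, 5])
    assert anchors.indices == (0, 5, 7)


def test_find_anchors_dummy_symbol(rocksalt_cube):
    relabeled = replace_surface(rocksalt_cube, "Cl", 1.0, "A")
    anchors = find_anchors(relabeled, "A")
    assert len(anchors) > 0
    assert all(relabeled.atoms[i].element == "A" for i in anchors.indices)


def test_find_anchors_errors(rocksalt_cube):
    with pytest.raises(ValueError):
        find_anchors(rocksalt_cube, "Xx")
    with pytest.raises(IndexError):
        find_anchors(rocksalt_cube, [999])


# ---------------------------------------------------------------- surface model


def test_cube_hull_vertices_and_facets(cube_corner_anchors):
    _, anchors = cube_corner_anchors
    sm = build_surface_model(anchors)
    assert len(sm.hull_vertices) == 8
    assert len(sm.facets) == 12  # 6 squares, each split into 2 triangles


def test_interior_point_excluded_from_hull():
    pts = np.vstack(
        [[[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], [[0.5, 0.5, 0.5]]]
    )
    anchors = AnchorSet(tuple(range(9)), pts)
    sm = build_surface_model(anchors)
    assert 8 not in sm.hull_vertices


def test_tetrahedron_hull_complete_adjacency():
    pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    anchors = AnchorSet(tuple(range(4)), pts)
    sm = build_surface_model(anchors)
    assert len(sm.hull_vertices) == 4
    assert len(sm.facets) == 4
    for a, b in itertools.combinations(range(4), 2):
        assert sm.edge_graph.has_edge(a, b)


def test_coplanar_anchors_raise_dimensionality_error():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
    with pytest.raises(DegenerateSurfaceError):
        build_surface_model(AnchorSet(tuple(range(4)), pts))


def test_facet_normals_point_outward(cube_corner_anchors):
    _, anchors = cube_corner_anchors
    sm = build_surface_model(anchors)
    centroid = anchors.positions.mean(axis=0)
    for tri, normal in sm.facets:
        face_center = anchors.positions[list(tri)].mean(axis=0)
        assert np.dot(normal, face_center - centroid) > 0


# ---------------------------------------------------------------- distances


def test_two_point_distance_matrix():
    anchors = AnchorSet((0, 1), np.array([[0.0, 0, 0], [3.0, 0, 0]]))
    D = distance_matrix(anchors)
    assert np.allclose(D.values, [[0, 3], [3, 0]])


def test_octahedron_over_surface_vs_through_space():
    """Opposite vertices: 2.0 through space, two hull edges (2*sqrt(2)) over
    the surface — matches the hand-enumerated shortest path."""
    pts = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
    )
    anchors = AnchorSet(tuple(range(6)), pts)
    sm = build_surface_model(anchors)
    Dt = distance_matrix(anchors)
    Ds = distance_matrix(anchors, sm, "over_surface")
    assert Dt[0, 1] == pytest.approx(2.0)
    assert Ds[0, 1] == pytest.approx(2 * math.sqrt(2))
    assert Ds[0, 2] == pytest.approx(math.sqrt(2))  # adjacent: one edge


@pytest.mark.parametrize("trial", range(10))
def test_over_surface_dominates_through_space_and_triangle_inequality(trial):
    rng = np.random.default_rng(100 + trial)
    pts = rng.normal(size=(12, 3)) * 5.0
    anchors = AnchorSet(tuple(range(len(pts))), pts)
    sm = build_surface_model(anchors)
    Dt = distance_matrix(anchors).values
    Ds = distance_matrix(anchors, sm, "over_surface").values
    assert np.all(Ds >= Dt - 1e-9)
    n = Ds.shape[0]
    for i, j, k in itertools.permutations(range(n), 3):
        assert Ds[i, j] <= Ds[i, k] + Ds[k, j] + 1e-9


# ---------------------------------------------------------------- selection


def test_select_full_set_any_mode(cube_corner_anchors):
    _, anchors = cube_corner_anchors
    D = distance_matrix(anchors)
    for mode in ("uniform", "cluster", "random"):
        sel = select_anchor_subset(anchors, D, 8, mode=mode, seed=0)
        assert sorted(sel.indices) == list(range(8))


def test_collinear_uniform_picks_the_ends():
    pts = np.array([[x, 0.0, 0.0] for x in range(4)])
    anchors = AnchorSet(tuple(range(4)), pts)
    D = distance_matrix(anchors)
    sel = select_anchor_subset(anchors, D, 2, mode="uniform")
    assert sel.indices == (0, 3)


def test_collinear_cluster_picks_adjacent():
    pts = np.array([[x, 0.0, 0.0] for x in range(4)])
    anchors = AnchorSet(tuple(range(4)), pts)
    D = distance_matrix(anchors)
    sel = select_anchor_subset(anchors, D, 2, mode="cluster")
    assert set(sel.indices) == {0, 1}


@pytest.mark.parametrize("mode", ["uniform", "cluster"])
@pytest.mark.parametrize("trial", range(8))
def test_greedy_matches_independent_recurrence(mode, trial):
    """Step-by-step oracle agreement on random <=12-point sets, both
    distance definitions."""
    rng = np.random.default_rng(trial)
    n = int(rng.integers(4, 13))
    pts = rng.normal(size=(n, 3)) * 4.0
    anchors = AnchorSet(tuple(range(n)), pts)
    for dist_mode in ("through_space", "over_surface"):
        sm = build_surface_model(anchors) if dist_mode == "over_surface" else None
        D = distance_matrix(anchors, sm, dist_mode)
        for k in (1, n // 2 or 1, n):
            got = select_anchor_subset(anchors, D, k, mode=mode)
            assert list(got.indices) == greedy_oracle(D.values, k, mode)


def test_uniform_k2_second_pick_is_weighted_farthest():
    rng = np.random.default_rng(77)
    pts = rng.normal(size=(10, 3)) * 3.0
    anchors = AnchorSet(tuple(range(10)), pts)
    D = distance_matrix(anchors)
    sel = select_anchor_subset(anchors, D, 2, mode="uniform")
    first = sel.indices[0]
    expected = min(
        (j for j in range(10) if j != first),
        key=lambda j: (math.exp(-D[j, first]), j),
    )
    assert sel.indices[1] == expected


def test_selection_permutation_equivariant():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(9, 3)) * 3.0
    anchors = AnchorSet(tuple(range(9)), pts)
    D = distance_matrix(anchors)
    sel = select_anchor_subset(anchors, D, 4, mode="uniform")
    perm = rng.permutation(9)
    anchors_p = AnchorSet(tuple(range(9)), pts[perm])
    D_p = distance_matrix(anchors_p)
    sel_p = select_anchor_subset(anchors_p, D_p, 4, mode="uniform")
    sites = {tuple(np.round(pts[i], 9)) for i in sel.indices}
    sites_p = {tuple(np.round(anchors_p.positions[i], 9)) for i in sel_p.indices}
    assert sites == sites_p


def test_random_mode_seeded_and_without_replacement():
    pts = np.random.default_rng(1).normal(size=(20, 3))
    anchors = AnchorSet(tuple(range(20)), pts)
    D = distance_matrix(anchors)
    a = select_anchor_subset(anchors, D, 7, mode="random", seed=5)
    b = select_anchor_subset(anchors, D, 7, mode="random", seed=5)
    c = select_anchor_subset(anchors, D, 7, mode="random", seed=6)
    assert a.indices == b.indices
    assert len(set(a.indices)) == 7
    assert a.indices != c.indices  # overwhelmingly likely under a new seed


def test_mixture_stages_compose():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(16, 3)) * 5
    anchors = AnchorSet(tuple(range(16)), pts)
    D = distance_matrix(anchors)
    sel = select_anchor_subset(anchors, D, 4, mode=[("uniform", 8), ("random", 4)], seed=2)
    stage1 = select_anchor_subset(anchors, D, 8, mode="uniform")
    assert set(sel.indices) <= set(stage1.indices)
    assert len(sel) == 4


def test_selection_k_bounds(cube_corner_anchors):
    _, anchors = cube_corner_anchors
    D = distance_matrix(anchors)
    with pytest.raises(ValueError):
        select_anchor_subset(anchors, D, 0)
    with pytest.raises(ValueError):
        select_anchor_subset(anchors, D, 9)


def test_uniform_spreads_and_cluster_packs_versus_random_baseline():
    """On lattice surfaces, uniform picks are farther apart and cluster picks
    closer together than seeded random subsets of equal size."""
    rng = np.random.default_rng(0)
    lattices = [
        build_rocksalt_cube(LatticeSpec(lattice_constant=a, repeats=(r, r, r)))
        for a, r in [(5.0, 2), (5.6, 2), (6.2, 2), (5.0, 3), (5.6, 3)]
    ]
    for mol in lattices:
        surf = surface_atom_indices(mol, "Cl")
        anchors = AnchorSet(tuple(surf), mol.positions[surf])
        D = distance_matrix(anchors)
        n, k = len(anchors), max(3, len(anchors) // 4)

        def mean_nn(local_idx):
            sub = D.values[np.ix_(local_idx, local_idx)].copy()
            np.fill_diagonal(sub, np.inf)
            return sub.min(axis=1).mean()

        uni = mean_nn([anchors.indices.index(i) for i in select_anchor_subset(anchors, D, k, "uniform").indices])
        clu = mean_nn([anchors.indices.index(i) for i in select_anchor_subset(anchors, D, k, "cluster").indices])
        randoms = [mean_nn(rng.choice(n, size=k, replace=False)) for _ in range(200)]
        assert uni >= max(randoms) - 1e-9
        assert clu <= min(randoms) + 1e-9


# ---------------------------------------------------------------- replace_surface


def test_replace_surface_full_fraction(rocksalt_cube):
    out = replace_surface(rocksalt_cube, "Cl", 1.0, "A")
    n_surf = len(surface_atom_indices(rocksalt_cube, "Cl"))
    assert out.formula()["A"] == n_surf
    assert np.allclose(out.positions, rocksalt_cube.positions)


def test_replace_surface_fraction_count():
    mol = build_rocksalt_cube(LatticeSpec(repeats=(3, 3, 3)))
    n_surf = len(surface_atom_indices(mol, "Cl"))
    out = replace_surface(mol, "Cl", 0.33, "A", mode="uniform", seed=1)
    assert out.formula()["A"] == int(0.33 * n_surf + 0.5)


def test_replace_surface_two_dummies_coexist():
    mol = build_rocksalt_cube(LatticeSpec(repeats=(3, 3, 3)))
    out = replace_surface(mol, "Na", 0.54, "A", seed=1)
    out = replace_surface(out, "Cl", 0.82, "B", seed=1)
    f = out.formula()
    n_na = len(surface_atom_indices(mol, "Na"))
    n_cl = len(surface_atom_indices(mol, "Cl"))
    assert f["A"] == int(0.54 * n_na + 0.5)
    assert f["B"] == int(0.82 * n_cl + 0.5)


def test_replace_surface_missing_element():
    mol = build_rocksalt_cube()
    with pytest.raises(ValueError):
        replace_surface(mol, "Xx", 0.5, "A")


# ---------------------------------------------------------------- core vectors


def test_cube_corner_vectors_point_outward(cube_corner_anchors):
    mol, anchors = cube_corner_anchors
    vecs = core_vectors(mol, anchors, "surface")
    centroid = anchors.positions.mean(axis=0)
    for row in range(len(anchors)):
        assert np.dot(vecs[row], anchors.positions[row] - centroid) > 0
        assert np.linalg.norm(vecs[row]) == pytest.approx(1.0)


def test_sphere_invert_negates(cube_corner_anchors):
    mol, anchors = cube_corner_anchors
    out = core_vectors(mol, anchors, "surface")
    inv = core_vectors(mol, anchors, "sphere_invert")
    assert np.allclose(inv, -out)


def test_face_atom_vector_is_face_normal():
    """A non-vertex atom in the middle of a cube face gets the face normal."""
    pts = [[i, j, k] for i in (0.0, 2.0) for j in (0.0, 2.0) for k in (0.0, 2.0)]
    pts.append([1.0, 1.0, 2.0])  # centre of the +z face
    pts = np.array(pts)
    mol = Molecule(atoms=[Atom("Cl", tuple(p)) for p in pts])
    anchors = AnchorSet(tuple(range(9)), pts)
    vecs = core_vectors(mol, anchors, "surface")
    assert np.allclose(vecs[8], [0, 0, 1], atol=1e-9)


def test_covalent_vector_along_bond():
    mol = Molecule(
        atoms=[Atom("C", (0.0, 0.0, 0.0)), Atom("H", (0.0, 0.0, 1.1))],
        bonds={(0, 1, 1.0)},
    )
    anchors = find_anchors(mol, "H")
    vecs = core_vectors(mol, anchors, "covalent")
    assert np.allclose(vecs[0], [0, 0, 1])


def test_covalent_vector_ambiguous_neighbours():
    mol = Molecule(
        atoms=[
            Atom("O", (0.0, 0.0, 0.0)),
            Atom("C", (-1.0, 0.0, 0.0)),
            Atom("C", (1.0, 0.0, 0.0)),
        ],
        bonds={(0, 1, 1.0), (0, 2, 1.0)},
    )
    anchors = find_anchors(mol, "O")
    with pytest.raises(ValueError):
        core_vectors(mol, anchors, "covalent")
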