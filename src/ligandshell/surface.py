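"""Scaffold anchor sites, convex-hull surface model, and site distribution.

The scaffold surface is idealized as the convex hull of the anchor
positions (Qhull via SciPy).  Distances between anchors are measured either
through space or *over the surface*: shortest paths on the graph of hull
edges, which better reflects how far apart two ligands are on opposite
facets of a nanocrystal.

Partial passivation reduces the anchor superset to ``k`` sites with a greedy
recurrence: each new site extremizes the crowding score
``S(j) = sum_{a picked} f(D[j, a])`` with the decreasing weight
``f(x) = exp(-x)`` (x in Å), so nearest neighbours dominate.  ``uniform``
picks the least crowded candidate (maximizing the weighted nearest-neighbour
distance), ``cluster`` the most crowded, ``random`` ignores geometry.  The
first pick scores against the whole superset.  Modes may be composed as an
ordered list of (mode, count) stages, each refining the previous stage's
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .molecule import Atom, Molecule

__all__ = [
    "AnchorSet",
    "SurfaceModel",
    "DistanceMatrix",
    "find_anchors",
    "build_surface_model",
    "distance_matrix",
    "select_anchor_subset",
    "replace_surface",
    "core_vectors",
    "surface_atom_indices",
]

#: default crowding weight, f(x) = e^-x with x in Å
def exp_weight(x: np.ndarray) -> np.ndarray:
    return np.exp(-np.asarray(x, dtype=float))


@dataclass(frozen=True)
class AnchorSet:
    """Anchor atoms of a scaffold: indices into the molecule + positions."""

    indices: tuple[int, ...]
    positions: np.ndarray  # (n, 3), Å

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("anchor indices must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.indices), 3):
            raise ValueError(f"positions shape {pos.shape} does not match {len(self.indices)} indices")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.indices)

    def subset(self, local: Sequence[int]) -> "AnchorSet":
        """New AnchorSet from local positions (0..n-1) within this set."""
        return AnchorSet(
            indices=tuple(self.indices[i] for i in local),
            positions=self.positions[list(local)],
        )


@dataclass(frozen=True)
class SurfaceModel:
    """Convex-hull polyhedron over anchor positions.

    ``hull_vertices`` are *local* anchor positions (0..n-1) on the hull;
    ``facets`` are triangles of local indices with outward unit normals;
    ``edge_graph`` is a Euclidean-weighted graph on all anchors: hull edges
    plus, for every non-vertex anchor, one edge to its nearest hull vertex.
    """

    hull_vertices: tuple[int, ...]
    facets: tuple[tuple[tuple[int, int, int], tuple[float, float, float]], ...]
    edge_graph: nx.Graph
    equations: np.ndarray  # Qhull facet plane equations (m, 4): n·x + d = 0


class DegenerateSurfaceError(ValueError):
    """Anchor positions are too flat/few to span a 3D hull."""


def find_anchors(scaffold: Molecule, spec: str | Sequence[int]) -> AnchorSet:
    """Anchor atoms by element symbol or explicit index list (ascending)."""
    if isinstance(spec, str):
        idx = [i for i, a in enumerate(scaffold.atoms) if a.element == spec]
        if not idx:
            raise ValueError(f"no atoms with symbol {spec!r} in scaffold {scaffold.name!r}")
    else:
        idx = sorted(int(i) for i in spec)
        if not idx:
            raise ValueError("empty anchor index list")
        for i in idx:
            if not (0 <= i < len(scaffold)):
                raise IndexError(f"anchor index {i} out of range for {len(scaffold)} atoms")
    pos = scaffold.positions[idx]
    return AnchorSet(indices=tuple(idx), positions=pos)


def build_surface_model(anchors: AnchorSet) -> SurfaceModel:
    """Convex hull + edge graph over the anchor positions."""
    if len(anchors) < 4:
        raise DegenerateSurfaceError(
            f"need at least 4 anchors for a 3D hull, got {len(anchors)}; "
            "use through-space distances instead"
        )
    try:
        hull = ConvexHull(anchors.positions)
    except QhullError as exc:
        raise DegenerateSurfaceError(
            "anchor positions are coplanar or collinear; a 3D surface model "
            "is undefined — use through-space distances instead"
        ) from exc

    centroid = anchors.positions.mean(axis=0)
    facets = []
    graph = nx.Graph()
    graph.add_nodes_from(range(len(anchors)))
    for simplex, eq in zip(hull.simplices, hull.equations):
        normal = eq[:3] / np.linalg.norm(eq[:3])
        # Qhull normals point outward already; enforce against the centroid.
        face_center = anchors.positions[simplex].mean(axis=0)
        if np.dot(normal, face_center - centroid) < 0:
            normal = -normal
        tri = tuple(int(v) for v in simplex)
        facets.append((tri, tuple(float(x) for x in normal)))
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])):
            w = float(np.linalg.norm(anchors.positions[a] - anchors.positions[b]))
            graph.add_edge(a, b, weight=w)

    vertices = tuple(int(v) for v in sorted(hull.vertices))
    vert_pos = anchors.positions[list(vertices)]
    tree = cKDTree(vert_pos)
    for i in range(len(anchors)):
        if i in hull.vertices or graph.degree(i) > 0:
            continue
        d, j = tree.query(anchors.positions[i])
        graph.add_edge(i, vertices[int(j)], weight=float(d))

    return SurfaceModel(
        hull_vertices=vertices,
        facets=tuple(facets),
        edge_graph=graph,
        equations=np.array(hull.equations, dtype=float),
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric anchor–anchor distances (Å), through space or over surface."""

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    def __getitem__(self, key):
        return self.values[key]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(
    anchors: AnchorSet, surface: SurfaceModel | None = None, mode: str = "through_space"
) -> DistanceMatrix:
    """Pairwise anchor distances, Euclidean or shortest-path along hull edges."""
    if mode == "through_space":
        diff = anchors.positions[:, None, :] - anchors.positions[None, :, :]
        return DistanceMatrix(np.linalg.norm(diff, axis=-1), mode)
    if mode != "over_surface":
        raise ValueError(f"unknown distance mode {mode!r}")
    if surface is None:
        raise ValueError("over_surface distances require a SurfaceModel")
    import scipy.sparse as sp
    from scipy.sparse.csgraph import shortest_path

    n = len(anchors)
    g = surface.edge_graph
    rows, cols, data = [], [], []
    for a, b, w in g.edges(data="weight"):
        rows += [a, b]
        cols += [b, a]
        data += [w, w]
    mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    d = shortest_path(mat, directed=False)
    if np.isinf(d).any():
        raise ValueError("surface edge graph is disconnected; over-surface distances undefined")
    return DistanceMatrix(d, mode)


def _greedy_select(
    D: np.ndarray, k: int, maximize_crowding: bool, weight: Callable[[np.ndarray], np.ndarray]
) -> list[int]:
    """Greedy extremization of the crowding score; lowest index wins ties."""
    n = D.shape[0]
    W = weight(D)
    np.fill_diagonal(W, 0.0)  # self term excluded everywhere
    # first pick scores against the entire superset
    crowd = W.sum(axis=1)
    pick = int(np.argmax(crowd) if maximize_crowding else np.argmin(crowd))
    picked = [pick]
    score = W[:, pick].copy()
    for _ in range(1, k):
        s = score.copy()
        s[picked] = -np.inf if maximize_crowding else np.inf
        nxt = int(np.argmax(s) if maximize_crowding else np.argmin(s))
        picked.append(nxt)
        score += W[:, nxt]
    return picked


def select_anchor_subset(
    anchors: AnchorSet,
    D: DistanceMatrix,
    k: int,
    mode: str | Sequence[tuple[str, int]] = "uniform",
    weight: Callable[[np.ndarray], np.ndarray] = exp_weight,
    seed: int = 42,
) -> AnchorSet:
    """Reduce the anchor superset to ``k`` sites.

    ``mode`` is ``uniform`` / ``cluster`` / ``random``, or an ordered list
    of ``(mode, count)`` stages composing them (the last stage must keep
    ``k`` sites).  Selection order is pick order; ties break to the lowest
    local index, making the result deterministic.
    """
    n = len(anchors)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if isinstance(mode, str):
        stages: list[tuple[str, int]] = [(mode, k)]
    else:
        stages = [(m, int(kk)) for m, kk in mode]
        if not stages or stages[-1][1] != k:
            raise ValueError(f"last mixture stage must select k={k} sites, got {stages}")

    rng = np.random.default_rng(seed)
    current = list(range(n))
    for m, kk in stages:
        if kk > len(current):
            raise ValueError(f"stage ({m}, {kk}) asks for more sites than available ({len(current)})")
        sub = D.values[np.ix_(current, current)]
        if m == "random":
            local = sorted(rng.choice(len(current), size=kk, replace=False).tolist())
        elif m in ("uniform", "cluster"):
            local = _greedy_select(sub, kk, maximize_crowding=(m == "cluster"), weight=weight)
        else:
            raise ValueError(f"unknown selection mode {m!r}")
        current = [current[i] for i in local]
    return anchors.subset(current)


def surface_atom_indices(scaffold: Molecule, element: str | None = None, tol: float = 0.5) -> list[int]:
    """Atoms lying on the scaffold's all-atom convex hull (within ``tol`` Å).

    An atom is a surface atom if its largest signed distance to the hull's
    facet planes exceeds ``-tol`` (i.e. it sits on or just below a facet).
    """
    pos = scaffold.positions
    hull = ConvexHull(pos)
    # signed distance to each facet plane; <= 0 inside
    signed = pos @ hull.equations[:, :3].T + hull.equations[:, 3]
    on_surface = signed.max(axis=1) > -tol
    out = [
        i
        for i in range(len(scaffold))
        if on_surface[i] and (element is None or scaffold.atoms[i].element == element)
    ]
    return out


def replace_surface(
    scaffold: Molecule,
    element: str,
    fraction: float,
    dummy: str,
    mode: str | Sequence[tuple[str, int]] = "uniform",
    seed: int = 42,
    distance: str = "through_space",
    weight: Callable[[np.ndarray], np.ndarray] = exp_weight,
    tol: float = 0.5,
) -> Molecule:
    """Relabel a distributed fraction of surface atoms of ``element`` as
    ``dummy`` anchor markers; coordinates and charges are untouched.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    surf = surface_atom_indices(scaffold, element, tol=tol)
    if not surf:
        raise ValueError(f"no surface atoms of element {element!r}")
    anchors = AnchorSet(indices=tuple(surf), positions=scaffold.positions[surf])
    k = max(1, int(fraction * len(surf) + 0.5))
    if k == len(surf):
        chosen = anchors
    else:
        surface = None
        if distance == "over_surface":
            surface = build_surface_model(anchors)
        D = distance_matrix(anchors, surface, distance)
        chosen = select_anchor_subset(anchors, D, k, mode=mode, seed=seed, weight=weight)
    out = scaffold.copy()
    from dataclasses import replace as _replace

    for i in chosen.indices:
        out.atoms[i] = _replace(out.atoms[i], element=dummy)
    return out


def core_vectors(
    scaffold: Molecule,
    anchors: AnchorSet,
    mode: str = "surface",
    surface: SurfaceModel | None = None,
    tol: float = 0.5,
) -> np.ndarray:
    """Outward unit vector per anchor, (n, 3).

    ``surface``: the mean outward normal of the hull facets whose planes pass
    through the anchor (anchors strictly inside the hull fall back to the
    centroid→anchor direction).  ``sphere_invert``: the same vectors negated,
    for grafting into concave cavities.  ``covalent``: the unit vector from
    an anchor's sole bonded neighbour toward the anchor.
    """
    n = len(anchors)
    if mode == "covalent":
        out = np.zeros((n, 3))
        for row, idx in enumerate(anchors.indices):
            nbrs = scaffold.neighbors(idx)
            if len(nbrs) != 1:
                raise ValueError(
                    f"covalent core vector for anchor {idx} needs exactly one bonded "
                    f"neighbour, found {len(nbrs)}"
                )
            v = anchors.positions[row] - scaffold.positions[nbrs[0]]
            nv = np.linalg.norm(v)
            if nv == 0:
                raise ValueError(f"anchor {idx} coincides with its neighbour")
            out[row] = v / nv
        return out
    if mode not in ("surface", "sphere_invert"):
        raise ValueError(f"unknown core-vector mode {mode!r}")
    if surface is None:
        surface = build_surface_model(anchors)
    centroid = anchors.positions.mean(axis=0)
    planes = surface.equations
    signed = anchors.positions @ planes[:, :3].T + planes[:, 3]  # (n, m)
    out = np.zeros((n, 3))
    normals = planes[:, :3] / np.linalg.norm(planes[:, :3], axis=1, keepdims=True)
    for row in range(n):
        touching = np.abs(signed[row]) <= tol
        if touching.any():
            v = normals[touching].mean(axis=0)
        else:
            v = anchors.positions[row] - centroid
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError(f"undefined outward direction for anchor {anchors.indices[row]}")
        out[row] = v / nv
    if mode == "sphere_invert":
        out = -out
    return out
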