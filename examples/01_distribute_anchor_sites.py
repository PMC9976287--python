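"""Distribute anchoring sites over a nanocrystal surface.

Builds a small rock-salt cube, detects its surface chlorides, and selects a
33% subset three ways: uniform (spread out), cluster (packed together), and
random.  The printed mean nearest-neighbour distances show what each mode
optimizes — uniform maximizes it, cluster minimizes it.
"""

import numpy as np

from ligandshell import AnchorSet, distance_matrix, select_anchor_subset, surface_atom_indices
from ligandshell.fixtures import LatticeSpec, build_rocksalt_cube

cube = build_rocksalt_cube(LatticeSpec(lattice_constant=5.64, repeats=(3, 3, 3)))
surface_cl = surface_atom_indices(cube, "Cl")
anchors = AnchorSet(tuple(surface_cl), cube.positions[surface_cl])
D = distance_matrix(anchors)
k = int(0.33 * len(anchors) + 0.5)

print(f"scaffold: {len(cube)} atoms, {len(anchors)} surface Cl, selecting {k} sites\n")
for mode in ("uniform", "cluster", "random"):
    sel = select_anchor_subset(anchors, D, k, mode=mode, seed=42)
    local = [anchors.indices.index(i) for i in sel.indices]
    sub = D.values[np.ix_(local, local)].copy()
    np.fill_diagonal(sub, np.inf)
    print(f"{mode:>8s}: mean nearest-neighbour distance {sub.min(axis=1).mean():.2f} A")

print(
    "\nuniform spreads ligands apart (large spacing), cluster packs them into"
    "\na patch (small spacing); random sits in between."
)
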