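# ligandshell

Automatic construction of composite chemical structures: take a large
scaffold — a semiconductor nanocrystal, a metal–organic-framework pore, an
organic core — and decorate it with organic ligands. Building such
ligand-passivated models by hand is the usual bottleneck before any
molecular-dynamics or electronic-structure calculation; `ligandshell`
automates the four steps a chemist would do manually:

1. **Scaffold anchors.** Anchoring sites are dummy atoms (any symbol, e.g.
   `A`) or a chosen element. For partial passivation the site superset is
   reduced to *k* sites with a greedy rule: each new site extremizes the
   crowding score S(j) = Σₐ f(Dⱼₐ) over already-picked sites *a*, with the
   decreasing weight f(x) = e⁻ˣ (x in Å). *Uniform* picks the least crowded
   site (maximizing the weighted nearest-neighbour distance), *cluster* the
   most crowded, *random* ignores geometry. Distances are Euclidean or
   geodesic over the scaffold's convex-hull surface (shortest paths on the
   Qhull edge graph).
2. **Ligand anchors.** Ligands are SMILES strings screened against
   functional-group substructure queries (thiol, carboxylic acid, hydroxyl,
   amine, phosphine, … — user-extensible). Every distinct group occurrence
   in a proto-ligand becomes its own ligand candidate; the optional *split*
   edit deprotonates the group (acid → carboxylate) or removes a leaving
   group (condensation, e.g. −OH off a carboxyl).
3. **Biased conformers.** Each ligand is pushed toward an elongated shape:
   fragment into linear chains (anchor in the largest), set backbone
   dihedrals anti-periplanar (syn when the central bond carries the anchor),
   then reattach fragment by fragment, keeping — out of three UFF-relaxed
   rotamers per bond — the one minimizing the perpendicular spread
   Σᵢ wᵢ·|rᵢ − (rᵢ·v)v| about the ligand vector **v** (the direction from
   the anchor minimizing that same score, iterated to self-consistency).
4. **Rigid attachment.** Each ligand vector is aligned to its site's
   outward core vector (mean adjacent hull-facet normal; negated for
   concave pores via `sphere_invert`; the anchor–neighbour bond direction
   for covalent scaffolds), the anchor is placed on the removed dummy, and
   the ligand is spun about the axis to maximize its minimum distance to
   previously placed ligands. Inter-ligand contacts below 1.4 Å are
   reported as warnings, and formal charges are book-kept exactly.

Everything runs on synthetic inputs generated in-package (rock-salt cubes,
(100) cuts of cubic double perovskites such as Cs₂AgInCl₆) — no downloads.

## Worked example

`examples/04_passivate_nanocrystal.py` passivates a ~2 nm Cs₂AgInCl₆ cut
with ethylammonium cations and acetate anions:

```
as-cut core: {'Cs': 125, 'Cl': 240, 'In': 32, 'Ag': 32} (net charge +13)
after Cs removal: net charge +0
dummy sites: 46 x A (was Cs), 79 x B (was Cl)

assembly: 1350 atoms, 125 ligands attached, net formal charge +0, 0 inter-ligand clash warning(s)
```

The as-cut Cs/Cl-terminated crystal is +13 in formal charges (Cs⁺, Ag⁺,
In³⁺, Cl⁻), so 13 surface Cs ions are removed before passivation; 54% of the
remaining surface Cs become dummy `A` sites (cations) and 82% of surface Cl
become `B` sites (anions). Replacing +1 sites by +1 ligands and −1 sites by
−1 ligands keeps the final 1350-atom model exactly neutral. The other
examples demonstrate site distribution (`01`), functional-group discovery on
mercaptopropionic acid (`02`), and the conformer bias on a branched decanoic
acid (`03`).

The same workflow is scriptable from a YAML file:

```bash
ligandshell run job.yaml --seed 42        # full pipeline
ligandshell run job.yaml --dry-run        # validate and list jobs
ligandshell distribute core.xyz --anchor Cl --fraction 0.33 --mode uniform
ligandshell conformer "CCCCC(CCCC)C(=O)O" --out ligand.xyz
```

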