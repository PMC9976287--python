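# Methods

This note records the models, defaults, and numerical choices behind
`ligandshell`, and what the synthetic test fixtures do and do not probe.

## Molecular representation

The pipeline's currency is a minimal `Molecule`: an ordered list of atoms
(element symbol, Cartesian position in Å, integer formal charge) plus an
undirected bond set `(i, j, order)`. Atom indices are 0-based internally and
1-based only in PDB serials. Any symbol outside the periodic table is a
*dummy* — an anchoring-site marker with zero mass and zero covalent radius —
and is carried verbatim through XYZ/PDB I/O. Conversion to RDKit (for
SMILES parsing, substructure matching, dihedral manipulation and UFF
relaxation) is restricted to all-real-element molecules, i.e. the organic
ligands; scaffolds with dummies never cross that boundary.

XYZ is the two-header-line dialect; extra columns are ignored on read, and
no bonds are inferred. XYZ carries no formal charges, so charge bookkeeping
across a file round trip requires PDB (HETATM charge columns + CONECT
records), which the tests and the end-to-end example use for ionic cores.
Ligand structure files without bonds get a covalent-radius distance
heuristic (bond if r < rᵢ + rⱼ + 0.45 Å).

## Site distribution

Partial passivation reduces the anchor superset to *k* sites greedily. The
crowding score of candidate *j* against a reference set is
S(j) = Σₐ f(D[j,a]) with the default weight f(x) = e⁻ˣ, x in Å, so nearest
neighbours dominate. `uniform` takes argmin S (equivalently, maximizes the
exponentially weighted nearest-neighbour distance), `cluster` argmax S; the
first pick scores against the entire superset; `random` draws without
replacement from a seeded generator (documented default seed 42). Ties
break to the lowest index, making every mode deterministic and
permutation-equivariant up to relabelling. A published phrasing of this
recurrence swaps argmax/argmin between the first and subsequent picks in a
way that contradicts its own stated goal (uniform = maximize the weighted
nearest-neighbour distance); the implementation follows the goal and the
tests pin the behaviour against an independent step-by-step evaluation.

Exhaustive search over all C(n, k) subsets is deliberately out of scope —
the greedy rule is the method. Modes compose as an ordered list of
`(mode, count)` stages, each refining the previous stage's selection (e.g.
uniform 20 → random 8); the grammar is this package's choice since only
free combinability, not syntax, is prescribed by the approach it follows.

Distances are either Euclidean (`through_space`) or over-surface: the
scaffold is idealized as the convex hull of the anchor positions (SciPy's
Qhull) and path lengths are shortest paths on the Euclidean-weighted graph
of hull edges. Anchors that are not hull vertices are connected to their
single nearest hull vertex — the simplest completion that keeps the graph
connected and preserves over-surface ≥ through-space. `replace_surface`
detects surface atoms as those within 0.5 Å of a hull facet plane (robust
to float noise on ideal lattices; configurable) and relabels
round(fraction × n_surface) of them as dummies, coordinates untouched.

Core vectors: for each anchor, the mean outward normal of the hull facets
whose planes pass through it (within the same 0.5 Å tolerance) — this gives
a face atom its face normal, an edge atom the mean of two, a corner atom
the mean of its adjacent facets; strictly interior anchors fall back to the
centroid→anchor direction. `sphere_invert` negates these for grafting into
concave cavities; `covalent` uses the unit vector from an anchor's sole
bonded neighbour toward the anchor and refuses ambiguous (0 or ≥2
neighbour) anchors.

## Ligand anchor discovery

Functional groups are substructure queries (SMARTS; plain SMILES inputs are
promoted to queries). Built-ins: hydroxyl `[OX2H][CX4]` (sp³-bound, so an
acid's OH is never double-counted), primary amine `[NX3;H2][#6]`, primary
ammonium `[NX4+;H3][#6]`, carboxylic acid `[CX3](=[OX1])[OX2H]` anchored at
the acidic O, thiol `[SX2H]`, phosphine `[PX3;H0]`. Symmetry-equivalent
matches are deduplicated by matched-atom set (one chemical site = one
ligand); the choice is switchable by matching with a single group and
inspecting `match_atoms`. Split defaults are per-group: acidic groups
(hydroxyl, acid, thiol) deprotonate by default (−1 on the anchor, one H
removed); neutral donors (amine, ammonium, phosphine) do not. An explicit
`remove_idx` set instead performs condensation-style removal (the listed
pattern atoms plus their hydrogens) with no charge adjustment. No
pKa-aware protonation or tautomer reasoning is attempted.

## Biased conformer search

Fragmentation cuts only rotatable single bonds between non-terminal heavy
atoms: ring systems, multiple-bond partners and terminal heavy atoms are
contracted into supernodes first, so e.g. a carboxylate never sheds its
oxygens. The anchor fragment is the heaviest chain through the anchor's
supernode; remaining branches are peeled off recursively as chains. Broken
bonds are hydrogen-capped at 1.09 Å on both sides.

Each fragment's backbone dihedrals are set to 180° (0° when the central
bond contains the anchor atom) with bond lengths and angles untouched.
Recombination reforms each bond at the sum of covalent radii and offers
three rotamers at −120°/0°/+120° from the incoming dihedral — the symmetric
choice for sp³ torsions, since only "three candidates" is prescribed.  Each
rotamer is relaxed by the optimizer (default: UFF, 400 iterations; the
contract is any `Molecule → Molecule` callable promising a local minimum,
which is also the hook for external tight-binding or DFT refinement, not
bundled). The rotamer minimizing the perpendicular-spread score is kept;
because the default relaxation is already unconstrained, no separate
final relaxation is needed after the choice.

The ligand vector minimizes Σᵢ wᵢ·|rᵢ − (rᵢ·v)v| with rᵢ measured from the
anchor atom. The default weight is wᵢ = 1 — the weighting is named but
never specified at the source, so unweighted is the neutral choice, with
e^(−|rᵢ|) available as an option. The initial guess is the direction from
the anchor to the mean atom position; Nelder–Mead refinement over spherical
angles is iterated to self-consistency (tolerance 1e-3 rad, ≤50 iterations
— values chosen here, none being prescribed), and the result never scores
worse than the guess.

## Attachment

The ligand anchor is placed exactly on the removed dummy's position (a
configurable radial offset along the core vector, default 0 Å, accommodates
conventions with an explicit anchor–surface bond length). The azimuth about
the core vector is sampled on a 24-point (15°) grid and the pose maximizing
the minimum distance to all previously placed ligands wins; sites are
processed in ascending index order for determinism. The starting azimuth is
canonicalized against the direction to the nearest other anchor, which
makes the whole construction equivariant under rigid motions of the
scaffold. Clash detection reports all inter-ligand atom pairs below 1.4 Å
as warnings — an invitation to a follow-up geometry optimization, never a
failure. For covalent grafting a bond record is written from the dummy's
scaffold neighbour to the ligand anchor atom (the natural reading for
condensation attachment; easily ignored downstream). Post-attachment
geometry optimization of the assembly and binding-energy workflows are out
of scope.

## Synthetic fixtures

Test scaffolds are finite, non-periodic clusters (the structures being
passivated are cuts, not crystals; no periodic boundary support). The
rock-salt builder tiles the conventional 8-atom cell. The double-perovskite
builder generates A-cation/halide-terminated (100) cuts of cubic elpasolite
A₂BB′X₆ on the half-cell parity grid, with rock-salt B/B′ ordering and
formal charges (+1, +1, +3, −1); the default lattice constant is 10.5 Å
(order-of-magnitude realistic for Cs₂AgInCl₆; the algorithms under test do
not depend on its exact value). With M = 13 A-planes per axis the cut is
the ~6 nm Cs₂₁₉₇Ag₈₆₄In₈₆₄Cl₅₆₁₆ composition with a +37 formal-charge
surplus, balanced by deleting 37 surface Cs; the test-suite example uses
M = 5 (~2 nm, 429 atoms) to keep the end-to-end run around a second.

What these fixtures do *not* emulate: surface reconstruction/relaxation,
faceting beyond (100), realistic ligand–surface bond lengths or binding
energetics, solvent, and finite temperature. Passing tests therefore show
the construction machinery is correct (counts, charges, geometry, and the
stated optimality properties), not that the assembled models are
equilibrium structures — they are starting points for force-field or
electronic-structure refinement, by design.

## Determinism and problem sizes

All randomness (distance-geometry embedding, random distribution mode)
flows from one config seed; identical configs and seeds produce
byte-identical outputs. The test suite runs in well under a minute on one
CPU: property sweeps use ≤12-point anchor sets where the greedy recurrence
is cross-checked exhaustively, 30 random branched acids for
fragmentation/recombination round trips, a 20-ligand elongation panel, and
the M = 5 end-to-end passivation. The acceptance script builds the full
M = 13 nanocrystal (9 541 atoms) for the charge arithmetic, which takes a
few seconds.

## Known limitations

- Ring-containing branches are kept rigid rather than linearized; the bias
  acts only on acyclic torsions.
- The azimuthal search is sequential and greedy; it does not revisit
  earlier ligands, so very dense shells can retain clashes (they are
  reported, not repaired).
- Over-surface distances follow hull edges only; for anchors far from hull
  vertices the geodesic is approximated through the nearest vertex.
- XYZ round trips drop formal charges by format limitation; use PDB when
  charge bookkeeping matters.
- SYBYL/InChI ligand input and trajectory/CIF formats are not supported.
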