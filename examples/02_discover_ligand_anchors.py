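"""Discover anchoring groups on a proto-ligand.

Mercaptopropionic acid (HS-CH2-CH2-COOH) carries both a thiol and a
carboxylic acid, so screening it against those two groups yields two
distinct ligands — one anchored through sulfur, one through the carboxylate
oxygen.  With split enabled each is deprotonated into its anion.
"""

from ligandshell import apply_split, match_functional_groups, molecule_from_smiles
from ligandshell.anchors import builtin_group

mpa = molecule_from_smiles("SCCC(=O)O")
groups = [builtin_group("thiol"), builtin_group("carboxylic acid")]

candidates = match_functional_groups(mpa, groups)
print(f"proto-ligand SCCC(=O)O -> {len(candidates)} ligand(s)\n")
for cand in candidates:
    split = apply_split(cand)
    anchor = split.edited.atoms[split.edited_anchor]
    print(
        f"  group {cand.group.name!r}: anchor atom {cand.anchor_atom} "
        f"({anchor.element}, charge {anchor.formal_charge:+d} after split, "
        f"net change {split.net_charge_change:+d})"
    )

print(
    "\nEach (proto-ligand, group occurrence) pair becomes its own ligand;"
    "\ndeprotonation turns the neutral groups into thiolate/carboxylate anchors."
)
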