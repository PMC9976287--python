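"""Structure I/O: XYZ and PDB files, plus SMILES → 3D molecules.

XYZ is the standard two-header-line dialect; extra columns after z are
ignored on read.  The element column is taken verbatim, so dummy anchor
symbols such as ``A`` or ``B`` survive a round trip.  PDB output uses
HETATM records and writes a CONECT entry for every stored bond.
"""

from __future__ import annotations

import os
from pathlib import Path

from .molecule import Atom, Molecule, from_rdkit

__all__ = [
    "read_structure",
    "write_structure",
    "molecule_from_smiles",
    "ParseError",
    "FormatError",
]


class ParseError(ValueError):
    """A structure file violated its format; carries the offending line."""


class FormatError(ValueError):
    """Unrecognized or unsupported file format."""


_FORMATS = ("xyz", "pdb")


def _guess_format(path: str | os.PathLike) -> str:
    ext = Path(path).suffix.lower().lstrip(".")
    if ext in _FORMATS:
        return ext
    raise FormatError(f"cannot infer format from extension {ext!r} of {path}")


def read_structure(path: str | os.PathLike, fmt: str = "auto") -> Molecule:
    """Read a molecule from an XYZ or PDB file.

    Atom order is preserved exactly as in the file; element symbols are kept
    verbatim (dummy symbols allowed).  XYZ reads produce no bonds; PDB reads
    recover bonds from CONECT records.
    """
    if fmt == "auto":
        fmt = _guess_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    text = Path(path).read_text()
    mol = _parse_xyz(text) if fmt == "xyz" else _parse_pdb(text)
    mol.name = Path(path).stem
    return mol


def _parse_xyz(text: str) -> Molecule:
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ file (line 1)")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}") from exc
    if len(lines) < n + 2:
        raise ParseError(f"line {len(lines)}: expected {n + 2} lines for {n} atoms")
    atoms = []
    for k in range(n):
        ln = lines[2 + k]
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"line {3 + k}: expected 'symbol x y z', got {ln!r}")
        try:
            pos = (float(parts[1]), float(parts[2]), float(parts[3]))
        except ValueError as exc:
            raise ParseError(f"line {3 + k}: bad coordinate in {ln!r}") from exc
        atoms.append(Atom(parts[0], pos))
    return Molecule(atoms=atoms)


def _parse_pdb(text: str) -> Molecule:
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    bonds: set[tuple[int, int]] = set()
    for lineno, ln in enumerate(text.splitlines(), start=1):
        rec = ln[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                serial = int(ln[6:11])
                x = float(ln[30:38])
                y = float(ln[38:46])
                z = float(ln[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed {rec} record") from exc
            element = ln[76:78].strip() or ln[12:16].strip().rstrip("0123456789")
            if not element:
                raise ParseError(f"line {lineno}: no element symbol")
            # columns 79-80: formal charge as e.g. "1+" / "2-"
            charge = 0
            cfield = ln[78:80].strip()
            if cfield:
                sign = -1 if cfield.endswith("-") else 1
                digits = cfield.rstrip("+-")
                if digits.isdigit():
                    charge = sign * int(digits)
            serial_to_index[serial] = len(atoms)
            atoms.append(Atom(element, (x, y, z), charge))
        elif rec == "CONECT":
            fields = ln[6:].split()
            if not fields:
                continue
            try:
                center = int(fields[0])
                partners = [int(f) for f in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed CONECT record") from exc
            for p in partners:
                bonds.add((min(center, p), max(center, p)))
    mol = Molecule(atoms=atoms)
    for a, b in bonds:
        if a in serial_to_index and b in serial_to_index:
            mol.add_bond(serial_to_index[a], serial_to_index[b])
    return mol


def write_structure(mol: Molecule, path: str | os.PathLike, fmt: str = "auto") -> None:
    """Write ``mol`` to an XYZ or PDB file (PDB includes CONECT bonds)."""
    if len(mol) == 0:
        raise ValueError("refusing to write an empty molecule")
    if fmt == "auto":
        fmt = _guess_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    text = _format_xyz(mol) if fmt == "xyz" else _format_pdb(mol)
    Path(path).write_text(text)


def _format_xyz(mol: Molecule) -> str:
    lines = [str(len(mol)), mol.name or ""]
    for a in mol.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<4s} {x:15.6f} {y:15.6f} {z:15.6f}")
    return "\n".join(lines) + "\n"


def _format_pdb(mol: Molecule) -> str:
    lines = []
    for i, a in enumerate(mol.atoms):
        x, y, z = a.position
        cfield = ""
        if a.formal_charge:
            cfield = f"{abs(a.formal_charge)}{'+' if a.formal_charge > 0 else '-'}"
        name = a.element[:4]
        lines.append(
            f"HETATM{i + 1:5d} {name:<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}{cfield:<2s}"
        )
    adjacency: dict[int, list[int]] = {}
    for i, j, _ in sorted(mol.bonds):
        adjacency.setdefault(i, []).append(j)
        adjacency.setdefault(j, []).append(i)
    for i in sorted(adjacency):
        partners = sorted(adjacency[i])
        for k in range(0, len(partners), 4):
            chunk = "".join(f"{p + 1:5d}" for p in partners[k : k + 4])
            lines.append(f"CONECT{i + 1:5d}{chunk}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def molecule_from_smiles(smiles: str, embed3d: bool = True, seed: int = 42) -> Molecule:
    """Build a molecule (explicit hydrogens) from a SMILES string.

    With ``embed3d`` a 3D conformation is generated with RDKit's distance
    geometry (ETKDG, deterministic for a given ``seed``) and relaxed with a
    few UFF steps.  Without it, coordinates are all-zero placeholders and
    only the chemical graph is meaningful.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    rd = Chem.AddHs(rd)
    if embed3d:
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) % (2**31 - 1)
        if AllChem.EmbedMolecule(rd, params) != 0:
            # fall back to unconstrained embedding for tricky inputs
            if AllChem.EmbedMolecule(rd, useRandomCoords=True, randomSeed=int(seed) % (2**31 - 1)) != 0:
                raise ValueError(f"3D embedding failed for SMILES {smiles!r}")
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.warning")
        try:
            AllChem.UFFOptimizeMolecule(rd, maxIters=200)
        except Exception:
            pass
        finally:
            RDLogger.EnableLog("rdApp.warning")
    else:
        conf = Chem.Conformer(rd.GetNumAtoms())
        rd.AddConformer(conf, assignId=True)
    mol = from_rdkit(rd, name=smiles)
    mol.properties["smiles"] = smiles
    return mol
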