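"""Tripos MOL2 serialization for probe molecules.

One ``@<TRIPOS>MOLECULE`` block is written per probe, in input order, with
ATOM and BOND sections.  Coordinates are printed with 4 decimal places;
SYBYL atom types are derived from the element plus aromatic-bond membership,
which is all a sphere-matching docking engine needs from these files.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyInputError, ParseError
from .ftmap import Atom, ProbeMolecule

__all__ = ["write_mol2", "parse_mol2"]

_SYBYL = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3", "H": "H"}


def _sybyl_type(element: str, idx: int, bonds) -> str:
    if element in ("C", "N") and any(o == "ar" and idx in (i, j) for i, j, o in bonds):
        return f"{element}.ar"
    return _SYBYL.get(element, element)


def write_mol2(molecules: list[ProbeMolecule], names: list[str] | None = None) -> str:
    """Serialize probe molecules to multi-molecule Tripos MOL2 text."""
    if not molecules:
        raise EmptyInputError("no molecules to write")
    if names is not None and len(names) != len(molecules):
        raise ValueError("names must match molecules in length")
    out: list[str] = []
    for m_idx, mol in enumerate(molecules):
        name = names[m_idx] if names else f"{mol.probe_type}_{m_idx + 1}"
        out.append("@<TRIPOS>MOLECULE")
        out.append(name)
        out.append(f"{len(mol.atoms):5d}{len(mol.bonds):6d}{1:6d}{0:6d}{0:6d}")
        out.append("SMALL")
        out.append("NO_CHARGES")
        out.append("")
        out.append("@<TRIPOS>ATOM")
        for i, atom in enumerate(mol.atoms, start=1):
            x, y, z = atom.coords
            sybyl = _sybyl_type(atom.element, i - 1, mol.bonds)
            out.append(f"{i:7d} {atom.name:<8s}{x:10.4f}{y:10.4f}{z:10.4f} "
                       f"{sybyl:<8s}{1:3d} {mol.probe_type:<8s}")
        out.append("@<TRIPOS>BOND")
        for b_idx, (i, j, order) in enumerate(mol.bonds, start=1):
            out.append(f"{b_idx:6d}{i + 1:6d}{j + 1:6d} {order:>4s}")
    return "\n".join(out) + "\n"


def parse_mol2(text: str) -> list[ProbeMolecule]:
    """Parse multi-molecule Tripos MOL2 text back into probe molecules.

    Elements are recovered from the SYBYL type (token before the first dot);
    the substructure-name column, when present, restores ``probe_type``.
    """
    molecules: list[ProbeMolecule] = []
    lines = text.splitlines()
    section = None
    name: str | None = None
    mol_lines_seen = 0
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, str]] = []

    def flush():
        nonlocal atoms, bonds, name
        if name is None:
            return
        probe_type = atoms[0].residue_name if atoms else name
        mol = ProbeMolecule(probe_type=probe_type, atoms=atoms, bonds=bonds)
        molecules.append(mol)
        atoms, bonds, name = [], [], None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].strip().upper()
            if section == "MOLECULE":
                flush()
                mol_lines_seen = 0
            continue
        if section == "MOLECULE":
            mol_lines_seen += 1
            if mol_lines_seen == 1:
                name = line.strip()
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"short ATOM record: {line!r}", line=lineno)
            try:
                atom_name = parts[1]
                x, y, z = (float(v) for v in parts[2:5])
                sybyl = parts[5]
            except ValueError as exc:
                raise ParseError(f"bad ATOM record: {exc}", line=lineno) from exc
            element = sybyl.split(".")[0].upper()
            element = element if len(element) <= 2 else element[:2]
            subst = parts[7] if len(parts) > 7 else (name or "UNK")
            atoms.append(Atom(serial=int(parts[0]), name=atom_name, element=element,
                              residue_name=subst, residue_seq=1, chain=" ",
                              coords=np.array([x, y, z]), is_het=True))
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"short BOND record: {line!r}", line=lineno)
            try:
                i, j = int(parts[1]) - 1, int(parts[2]) - 1
            except ValueError as exc:
                raise ParseError(f"bad BOND record: {exc}", line=lineno) from exc
            bonds.append((i, j, parts[3]))
    flush()
    return molecules
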