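"""Structure file I/O: TRIPOS MOL2 and SD (V2000) readers/writers.

MOL2 is handled by a small reader/writer pair of our own (partial charges
live in the ATOM record's charge column; conformer energies in the MOLECULE
comment line as ``E_REL_KCAL=<x>``).  SD files go through RDKit, with partial
charges in a ``PARTIAL_CHARGES`` tag and energies in ``E_REL_KCAL``.
Multi-record files yield one molecule per record; consecutive records with
the same name and topology can be grouped into conformer ensembles.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .chem import (AMIDE_ORDER, AROMATIC_ORDER, ConformerEnsemble, Molecule,
                   from_rdkit, to_rdkit)


class ParseError(ValueError):
    """A record in a structure file could not be parsed."""


_MOL2_BOND_CODES = {"1": 1.0, "2": 2.0, "3": 3.0, "ar": AROMATIC_ORDER,
                    "am": AMIDE_ORDER, "du": 1.0, "un": 1.0, "nc": 1.0}
_CODE_TO_MOL2 = {1.0: "1", 2.0: "2", 3.0: "3", AROMATIC_ORDER: "ar",
                 AMIDE_ORDER: "am"}


def read_molecules(path: str, format: Optional[str] = None) -> list[Molecule]:
    """Read all molecules from a MOL2 or SD file (format inferred from the
    extension when not given).  An empty file yields an empty list."""
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"mol2": "mol2", "sdf": "sdf", "sd": "sdf", "mol": "sdf"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if format == "mol2":
        return read_mol2(path)
    if format == "sdf":
        return read_sdf(path)
    raise ValueError(f"unknown format {format!r}")


def write_molecules(path: str, mols: list[Molecule],
                    format: Optional[str] = None) -> None:
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"mol2": "mol2", "sdf": "sdf", "sd": "sdf"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if format == "mol2":
        write_mol2(path, mols)
    elif format == "sdf":
        write_sdf(path, mols)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# MOL2
# ---------------------------------------------------------------------------

def read_mol2(path: str) -> list[Molecule]:
    with open(path) as fh:
        text = fh.read()
    records = text.split("@<TRIPOS>MOLECULE")
    mols = []
    for k, rec in enumerate(records[1:]):
        try:
            mols.append(_parse_mol2_record(rec))
        except Exception as exc:  # noqa: BLE001 - rewrap with record index
            raise ParseError(f"MOL2 record {k} in {path!r}: {exc}") from exc
    return mols


def _parse_mol2_record(rec: str) -> Molecule:
    lines = rec.splitlines()
    # header: name line, counts line, mol type, charge type, [comment]
    body = [ln for ln in lines if not ln.startswith("#")]
    name = body[1].strip() if len(body) > 1 else ""
    counts = body[2].split()
    n_atoms, n_bonds = int(counts[0]), int(counts[1]) if len(counts) > 1 else 0
    charge_type = body[4].strip() if len(body) > 4 else "NO_CHARGES"
    energy = None
    for ln in body[5:8]:
        if "E_REL_KCAL=" in ln:
            energy = float(ln.split("E_REL_KCAL=")[1].split()[0])
            break
        if ln.startswith("@<TRIPOS>"):
            break

    def section(tag: str) -> list[str]:
        out, active = [], False
        for ln in lines:
            s = ln.strip()
            if s.startswith("@<TRIPOS>"):
                active = s == f"@<TRIPOS>{tag}"
                continue
            if active and s:
                out.append(s)
        return out

    atom_lines = section("ATOM")
    if len(atom_lines) < n_atoms:
        raise ValueError(f"expected {n_atoms} atoms, found {len(atom_lines)}")
    elements, coords, charges = [], [], []
    for ln in atom_lines[:n_atoms]:
        parts = ln.split()
        x, y, z = map(float, parts[2:5])
        sybyl = parts[5]
        elements.append(sybyl.split(".")[0])
        coords.append((x, y, z))
        charges.append(float(parts[8]) if len(parts) > 8 else 0.0)
    bonds = []
    for ln in section("BOND")[:n_bonds]:
        parts = ln.split()
        i, j = int(parts[1]) - 1, int(parts[2]) - 1
        code = _MOL2_BOND_CODES.get(parts[3].lower())
        if code is None:
            raise ValueError(f"unknown bond type {parts[3]!r}")
        bonds.append((i, j, code))
    has_charges = charge_type.upper() != "NO_CHARGES"
    return Molecule(name=name, elements=elements, coords=np.array(coords),
                    bonds=bonds, charges=np.array(charges), has_charges=has_charges,
                    energy=energy)


def _sybyl_type(mol: Molecule, i: int) -> str:
    e = mol.elements[i]
    orders = [o for a, b, o in mol.bonds if i in (a, b)]
    if e in ("C", "N"):
        if AROMATIC_ORDER in orders:
            return f"{e}.ar"
        if 3.0 in orders:
            return f"{e}.1"
        if 2.0 in orders:
            return f"{e}.2"
        if e == "N" and AMIDE_ORDER in orders:
            return "N.am"
        return f"{e}.3"
    if e == "O":
        return "O.2" if 2.0 in orders else "O.3"
    if e == "S":
        return "S.3"
    if e == "P":
        return "P.3"
    return e


def write_mol2(path: str, mols: list[Molecule]) -> None:
    out = []
    for mol in mols:
        charges = mol.charges if mol.charges is not None else np.zeros(mol.n_atoms)
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.name or "UNNAMED")
        out.append(f"{mol.n_atoms:>5d} {len(mol.bonds):>5d}     1     0     0")
        out.append("SMALL")
        out.append("USER_CHARGES" if mol.has_charges or mol.charges is not None
                   else "NO_CHARGES")
        if mol.energy is not None:
            out.append(f"E_REL_KCAL={mol.energy:.6f}")
        else:
            out.append("")
        out.append("@<TRIPOS>ATOM")
        for i in range(mol.n_atoms):
            x, y, z = mol.coords[i]
            out.append(f"{i + 1:>7d} {mol.elements[i]}{i + 1:<4} "
                       f"{x:>12.6f} {y:>12.6f} {z:>12.6f} "
                       f"{_sybyl_type(mol, i):<6} 1 LIG1 {charges[i]:>10.6f}")
        out.append("@<TRIPOS>BOND")
        for k, (i, j, order) in enumerate(mol.bonds):
            code = _CODE_TO_MOL2.get(order, "1")
            out.append(f"{k + 1:>6d} {i + 1:>5d} {j + 1:>5d} {code:>4}")
        out.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(out))


# ---------------------------------------------------------------------------
# SD
# ---------------------------------------------------------------------------

def read_sdf(path: str) -> list[Molecule]:
    from rdkit import Chem

    mols = []
    with open(path, "rb") as fh:
        supplier = Chem.ForwardSDMolSupplier(fh, removeHs=False, sanitize=True)
        for k, rd in enumerate(supplier):
            if rd is None:
                raise ParseError(f"SD record {k} in {path!r} failed to parse")
            mol = from_rdkit(rd)
            if rd.HasProp("PARTIAL_CHARGES"):
                q = np.array([float(v) for v in
                              rd.GetProp("PARTIAL_CHARGES").split()])
                if q.shape != (mol.n_atoms,):
                    raise ParseError(
                        f"SD record {k}: charge tag length {q.size} != "
                        f"{mol.n_atoms} atoms")
                mol.charges = q
                mol.has_charges = True
            if rd.HasProp("E_REL_KCAL"):
                mol.energy = float(rd.GetProp("E_REL_KCAL"))
            for prop in rd.GetPropNames():
                if prop not in ("PARTIAL_CHARGES", "E_REL_KCAL"):
                    mol.tags[prop] = rd.GetProp(prop)
            mols.append(mol)
    return mols


def write_sdf(path: str, mols: list[Molecule]) -> None:
    from rdkit import Chem

    writer = Chem.SDWriter(path)
    writer.SetKekulize(True)
    try:
        for mol in mols:
            rd = to_rdkit(mol)
            if mol.charges is not None:
                rd.SetProp("PARTIAL_CHARGES",
                           " ".join(f"{q:.6f}" for q in mol.charges))
            if mol.energy is not None:
                rd.SetProp("E_REL_KCAL", f"{mol.energy:.6f}")
            for k, v in mol.tags.items():
                rd.SetProp(str(k), str(v))
            writer.write(rd)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Conformer grouping
# ---------------------------------------------------------------------------

def group_conformers(mols: list[Molecule]) -> list[ConformerEnsemble]:
    """Group molecules sharing name and topology into conformer ensembles.

    Energies come from per-record ``E_REL_KCAL`` annotations (default 0) and
    are re-based so the lowest conformer in each ensemble sits at 0.
    """
    groups: list[list[Molecule]] = []
    for mol in mols:
        placed = False
        for g in groups:
            ref = g[0]
            if (mol.name == ref.name and mol.elements == ref.elements
                    and mol.bonds == ref.bonds):
                g.append(mol)
                placed = True
                break
        if not placed:
            groups.append([mol])
    ensembles = []
    for g in groups:
        energies = np.array([m.energy if m.energy is not None else 0.0
                             for m in g])
        energies = energies - energies.min()
        ensembles.append(ConformerEnsemble(g[0], [m.coords for m in g], energies))
    return ensembles
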