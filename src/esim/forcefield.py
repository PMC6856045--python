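"""Thin MMFF94 helpers (RDKit) for fixture energies and strain re-evaluation."""

from __future__ import annotations

from typing import Optional

import numpy as np


def mmff_energy(rd_mol, coords: np.ndarray) -> Optional[float]:
    """MMFF94 single-point energy (kcal/mol) of ``rd_mol`` at ``coords``;
    None when the molecule cannot be typed."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit.Geometry import Point3D

    mol = Chem.Mol(rd_mol)
    if mol.GetNumConformers() == 0:
        conf = Chem.Conformer(mol.GetNumAtoms())
        mol.AddConformer(conf, assignId=True)
    conf = mol.GetConformer()
    for i, xyz in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        return None
    ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf.GetId())
    if ff is None:
        return None
    return float(ff.CalcEnergy())
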