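"""Overlap metrics for aligned ligand pairs and symmetry-corrected RMSD.

Molecular overlap (MO) is the fraction of subject atoms whose centers fall
inside the target's van der Waals volume; direct atomic overlap (DAO) is the
fraction of subject atoms with at least three-quarters of their own van der
Waals volume inside a *single* target atom.  A pair is a tractable alignment
problem when MO >= 0.8 or DAO >= 0.5; high MO with low DAO marks the hard
"dissimilar scaffolds occupying the same space" regime, high DAO the easy
shared-scaffold regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

import networkx as nx
import numpy as np

from .chem import Molecule

MO_THRESHOLD = 0.8
DAO_THRESHOLD = 0.5
DAO_VOLUME_FRACTION = 0.75
AUTOMORPHISM_CAP = 10_000


@dataclass
class OverlapReport:
    mo: float
    dao: float
    mo_flags: np.ndarray
    dao_flags: np.ndarray

    @property
    def tractable(self) -> bool:
        return self.mo >= MO_THRESHOLD or self.dao >= DAO_THRESHOLD

    @property
    def label(self) -> str:
        return classify_pair(self)


def sphere_overlap_fraction(r1: float, r2: float, d: float) -> float:
    """Fraction of sphere 1's volume inside sphere 2 (analytic lens)."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        if r1 <= r2:
            return 1.0
        return (r2 / r1) ** 3
    lens = (np.pi * (r1 + r2 - d) ** 2
            * (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
            / (12.0 * d))
    return float(np.clip(lens / ((4.0 / 3.0) * np.pi * r1 ** 3), 0.0, 1.0))


def _check_radii(*mols: Molecule) -> None:
    for m in mols:
        if m.radii is None:
            raise ValueError(f"molecule {m.name!r} needs radii for overlap metrics")


def _atom_selection(mol: Molecule, include_hydrogens: bool) -> np.ndarray:
    return (np.ones(mol.n_atoms, dtype=bool) if include_hydrogens
            else mol.heavy_mask)


def molecular_overlap(subject: Molecule, target: Molecule,
                      include_hydrogens: bool = True) -> float:
    """MO: fraction of subject atom centers inside any target atom sphere."""
    return compute_overlap(subject, target, include_hydrogens).mo


def direct_atomic_overlap(subject: Molecule, target: Molecule,
                          include_hydrogens: bool = True) -> float:
    """DAO: fraction of subject atoms with >= 75% of their volume inside a
    single target atom."""
    return compute_overlap(subject, target, include_hydrogens).dao


def compute_overlap(subject: Molecule, target: Molecule,
                    include_hydrogens: bool = True) -> OverlapReport:
    _check_radii(subject, target)
    sel = _atom_selection(subject, include_hydrogens)
    s_xyz = subject.coords[sel]
    s_r = subject.radii[sel]
    d = np.linalg.norm(s_xyz[:, None, :] - target.coords[None, :, :], axis=2)
    mo_flags = np.any(d <= target.radii[None, :], axis=1)
    frac = np.zeros(d.shape)
    for j in range(target.n_atoms):
        for i in range(d.shape[0]):
            frac[i, j] = sphere_overlap_fraction(s_r[i], target.radii[j], d[i, j])
    dao_flags = frac.max(axis=1) >= DAO_VOLUME_FRACTION
    return OverlapReport(mo=float(mo_flags.mean()), dao=float(dao_flags.mean()),
                         mo_flags=mo_flags, dao_flags=dao_flags)


def classify_pair(report: OverlapReport) -> str:
    """Tractability class from the MO >= 0.8 / DAO >= 0.5 thresholds."""
    hi_mo = report.mo >= MO_THRESHOLD
    hi_dao = report.dao >= DAO_THRESHOLD
    if hi_mo and hi_dao:
        return "high-MO/high-DAO"
    if hi_mo:
        return "high-MO/low-DAO"
    if hi_dao:
        return "low-MO/high-DAO"
    return "intractable"


# ---------------------------------------------------------------------------
# Symmetry-corrected RMSD
# ---------------------------------------------------------------------------

def _heavy_graph(mol: Molecule) -> tuple[nx.Graph, list[int]]:
    heavy_idx = [i for i in range(mol.n_atoms) if mol.elements[i] != "H"]
    remap = {a: k for k, a in enumerate(heavy_idx)}
    g = nx.Graph()
    for a in heavy_idx:
        g.add_node(remap[a], element=mol.elements[a])
    for i, j, order in mol.bonds:
        if i in remap and j in remap:
            g.add_edge(remap[i], remap[j], order=order)
    return g, heavy_idx


def _automorphisms(g: nx.Graph, cap: int = AUTOMORPHISM_CAP):
    nm = nx.algorithms.isomorphism.categorical_node_match("element", "")
    em = nx.algorithms.isomorphism.categorical_edge_match("order", 0.0)
    gm = nx.algorithms.isomorphism.GraphMatcher(g, g, node_match=nm,
                                                edge_match=em)
    return list(islice(gm.isomorphisms_iter(), cap + 1))


def symmetry_rmsd(predicted: Molecule, reference: Molecule) -> float:
    """Heavy-atom RMSD minimized over element/bond-order-preserving graph
    automorphisms; no re-superposition (poses share a frame).

    Automorphism enumeration is capped at 10^4; beyond the cap the minimum
    over the enumerated prefix is returned (an upper bound on the true
    symmetry-corrected value).
    """
    if (predicted.elements != reference.elements
            or predicted.bonds != reference.bonds):
        raise ValueError("molecules must share topology for RMSD")
    g, heavy_idx = _heavy_graph(predicted)
    pred = predicted.coords[heavy_idx]
    ref = reference.coords[heavy_idx]
    autos = _automorphisms(g)
    if len(autos) > AUTOMORPHISM_CAP:
        autos = autos[:AUTOMORPHISM_CAP]
    best = np.inf
    n = len(heavy_idx)
    for mapping in autos:
        perm = np.array([mapping[k] for k in range(n)])
        rmsd = float(np.sqrt(np.mean(np.sum((pred - ref[perm]) ** 2, axis=1))))
        best = min(best, rmsd)
    return best
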