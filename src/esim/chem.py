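"""Molecular data model: atoms, bonds, polar features, conformer ensembles.

The model is deliberately small: numpy coordinate/charge/radius arrays plus a
bond list, with hydrogen-bond donors and acceptors perceived by an explicit
valence rule table (:data:`esim.params.POLAR_RULES`).  RDKit is used for
partial-charge assignment and for building fixture molecules; an optional
handle to the originating RDKit molecule is carried along for force-field
strain re-evaluation, but nothing in the similarity kernel depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .params import POLAR_RULES, VDW_RADII

# Bond order codes: 1.0 single, 2.0 double, 3.0 triple, 1.5 aromatic,
# 1.25 amide (TRIPOS "am").
AROMATIC_ORDER = 1.5
AMIDE_ORDER = 1.25


class UnknownElementError(ValueError):
    """Raised when an element has no entry in the radius table."""


@dataclass(frozen=True)
class DonorFeature:
    """A hydrogen-bond donor: the proton and its attached heavy atom."""

    proton: int
    base: int


@dataclass(frozen=True)
class AcceptorFeature:
    """A hydrogen-bond acceptor atom and the atoms bonded to it.

    The acceptor's intrinsic direction is the unit vector from the acceptor
    toward the centroid of its bonded neighbors; the lone-pair direction
    points the opposite way, so an observer collinear with that axis on the
    lone-pair side sees an angle of 180 degrees at the acceptor.
    """

    index: int
    neighbors: tuple[int, ...]

    def direction(self, coords: np.ndarray) -> np.ndarray:
        """Unit vector acceptor -> centroid of bonded neighbors."""
        centroid = coords[list(self.neighbors)].mean(axis=0)
        v = centroid - coords[self.index]
        n = float(np.linalg.norm(v))
        if n < 1e-12:
            raise ValueError("degenerate acceptor geometry")
        return v / n


@dataclass
class Molecule:
    """A small molecule: elements, 3D coordinates, charges, radii, bonds.

    ``bonds`` is a list of ``(i, j, order)`` with the order codes above.
    ``formal_charges`` are integers per atom; ``charges`` are partial charges
    in units of e.  ``has_charges`` records whether charges were assigned or
    merely defaulted to zero (e.g. an input file without a charge column).
    """

    name: str
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    charges: Optional[np.ndarray] = None
    radii: Optional[np.ndarray] = None
    formal_charges: Optional[np.ndarray] = None
    donors: list[DonorFeature] = field(default_factory=list)
    acceptors: list[AcceptorFeature] = field(default_factory=list)
    has_charges: bool = False
    energy: Optional[float] = None  # conformer energy annotation, kcal/mol
    tags: dict = field(default_factory=dict)  # free-form SD-tag annotations
    rd_mol: object = None  # optional RDKit handle; never required downstream

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if self.coords.shape[0] != n:
            raise ValueError("coords/elements length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise ValueError("charge list length must equal atom count")
        if self.formal_charges is not None:
            self.formal_charges = np.asarray(self.formal_charges, dtype=int)
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if np.any(self.radii <= 0):
                raise ValueError("radii must be positive")

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements], dtype=bool)

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def net_charge(self) -> float:
        if self.charges is None:
            return 0.0
        return float(self.charges.sum())

    # -- copies and rigid motion ---------------------------------------

    def copy(self) -> "Molecule":
        return replace(
            self,
            elements=list(self.elements),
            coords=self.coords.copy(),
            bonds=list(self.bonds),
            charges=None if self.charges is None else self.charges.copy(),
            radii=None if self.radii is None else self.radii.copy(),
            formal_charges=(None if self.formal_charges is None
                            else self.formal_charges.copy()),
            donors=list(self.donors),
            acceptors=list(self.acceptors),
            tags=dict(self.tags),
        )

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "Molecule":
        """Return a copy with coordinates ``R x + t``."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + translation
        return out

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if out.coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        return out


def assign_radii_and_charges(mol: Molecule,
                             charge_model: str = "gasteiger") -> Molecule:
    """Assign van der Waals radii (Bondi table) and partial charges.

    ``charge_model`` is ``"gasteiger"`` (default), ``"mmff"`` or ``"keep"``
    (leave whatever charges the input carried).  Charge assignment conserves
    the molecule's total formal charge to better than 0.01 e.
    """
    out = mol.copy()
    radii = []
    for e in mol.elements:
        if e not in VDW_RADII:
            raise UnknownElementError(f"no van der Waals radius for element {e!r}")
        radii.append(VDW_RADII[e])
    out.radii = np.array(radii)

    if charge_model == "keep":
        if out.charges is None:
            out.charges = np.zeros(mol.n_atoms)
        return out

    rd = mol.rd_mol if mol.rd_mol is not None else to_rdkit(mol)
    from rdkit.Chem import AllChem

    if charge_model == "gasteiger":
        AllChem.ComputeGasteigerCharges(rd)
        q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rd.GetAtoms()])
    elif charge_model == "mmff":
        props = AllChem.MMFFGetMoleculeProperties(rd)
        if props is None:
            raise ValueError(f"MMFF cannot type molecule {mol.name!r}")
        q = np.array([props.GetMMFFPartialCharge(i) for i in range(rd.GetNumAtoms())])
    else:
        raise ValueError(f"unknown charge model {charge_model!r}")
    if not np.all(np.isfinite(q)):
        raise ValueError(f"charge model produced non-finite charges for {mol.name!r}")
    out.charges = q
    out.has_charges = True
    out.rd_mol = rd
    return out


def perceive_polar_features(mol: Molecule,
                            rules: dict = POLAR_RULES) -> Molecule:
    """Perceive hydrogen-bond donors and acceptors from the valence table.

    Donors: every hydrogen bonded to N, O or S, paired with that heavy atom.
    Acceptors: N or O with a sterically available lone pair under the simple
    degree rule in ``rules`` (pyridine-type N and any O accept; amide and
    sp3 N, with three neighbors, do not), excluding positively charged atoms.
    The result depends only on topology, not on atom order or pose.
    """
    out = mol.copy()
    nbrs = mol.neighbor_lists()
    fcs = (mol.formal_charges if mol.formal_charges is not None
           else np.zeros(mol.n_atoms, dtype=int))

    donors: list[DonorFeature] = []
    acceptors: list[AcceptorFeature] = []
    for i, e in enumerate(mol.elements):
        if e == "H":
            for j in nbrs[i]:
                if mol.elements[j] in rules["donor_heavy"]:
                    donors.append(DonorFeature(proton=i, base=j))
        elif e in rules["acceptor_elements"]:
            if fcs[i] > 0 or not nbrs[i]:
                continue
            max_deg = (rules["n_acceptor_max_degree"] if e == "N"
                       else rules["o_acceptor_max_degree"])
            if len(nbrs[i]) <= max_deg:
                acceptors.append(AcceptorFeature(index=i,
                                                 neighbors=tuple(sorted(nbrs[i]))))
    out.donors = donors
    out.acceptors = acceptors
    return out


def strain_penalty(conf_energy: float, strain_const: float = 0.05) -> float:
    """Strain term: minus ``strain_const`` times the conformer energy (>= 0)
    above the ensemble's global minimum.  Always <= 0."""
    if conf_energy < 0:
        raise ValueError("conformer energy above global minimum cannot be negative")
    return -strain_const * conf_energy


@dataclass
class ConformerEnsemble:
    """A molecule's conformers with energies relative to the global minimum.

    All conformers share the topology (elements, bonds, charges, features) of
    ``molecule``; ``energies`` are kcal/mol above the lowest-energy conformer,
    so ``energies.min() == 0``.
    """

    molecule: Molecule
    conformers: list[np.ndarray]
    energies: np.ndarray

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        self.conformers = [np.asarray(c, dtype=float).reshape(-1, 3)
                           for c in self.conformers]
        n = self.molecule.n_atoms
        for c in self.conformers:
            if c.shape[0] != n:
                raise ValueError("conformer does not match topology")
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (len(self.conformers),):
            raise ValueError("one energy per conformer required")
        if np.any(self.energies < 0):
            raise ValueError("relative conformer energies must be >= 0")
        if abs(self.energies.min()) > 1e-9:
            raise ValueError("global-minimum conformer must have energy 0")

    def __len__(self) -> int:
        return len(self.conformers)

    def molecule_at(self, i: int) -> Molecule:
        return self.molecule.with_coords(self.conformers[i])

    def subset(self, indices: Sequence[int]) -> "ConformerEnsemble":
        confs = [self.conformers[i] for i in indices]
        en = self.energies[list(indices)]
        en = en - en.min()
        return ConformerEnsemble(self.molecule, confs, en)


def randomize_pose(ens: ConformerEnsemble, seed: int) -> ConformerEnsemble:
    """Apply a seeded random rigid transform to every conformer.

    Removes all memory of the input frame while preserving internal geometry
    exactly (rotation about each conformer's centroid plus a translation drawn
    uniformly from [-10, 10] A per axis).
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    confs = []
    for c in ens.conformers:
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-10.0, 10.0, size=3)
        center = c.mean(axis=0)
        confs.append((c - center) @ rot.T + center + t)
    return ConformerEnsemble(ens.molecule, confs, ens.energies.copy())


# ---------------------------------------------------------------------------
# RDKit bridging
# ---------------------------------------------------------------------------

_RD_ORDER_TO_CODE = {
    "SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": AROMATIC_ORDER,
}


def from_rdkit(rd, conf_id: int = -1, name: Optional[str] = None) -> Molecule:
    """Convert an RDKit molecule (with a 3D conformer) to a :class:`Molecule`."""
    from rdkit import Chem

    conf = rd.GetConformer(conf_id)
    coords = np.array(conf.GetPositions(), dtype=float)
    elements = [a.GetSymbol() for a in rd.GetAtoms()]
    fcs = np.array([a.GetFormalCharge() for a in rd.GetAtoms()], dtype=int)
    bonds = []
    for b in rd.GetBonds():
        code = _RD_ORDER_TO_CODE.get(str(b.GetBondType()), 1.0)
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), code))
    if name is None:
        name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
    return Molecule(name=name, elements=elements, coords=coords, bonds=bonds,
                    formal_charges=fcs, rd_mol=rd)


def to_rdkit(mol: Molecule):
    """Build a sanitized RDKit molecule from topology and coordinates.

    Formal charges are taken from the molecule when present; otherwise a
    minimal inference is applied (tetravalent N -> +1, singly bonded O with
    bond order 1 and no proton -> -1) so that common charged groups read from
    charge-free formats sanitize correctly.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    em = Chem.RWMol()
    fcs = mol.formal_charges
    if fcs is None:
        fcs = _infer_formal_charges(mol)
    for e, fc in zip(mol.elements, fcs):
        a = Chem.Atom(e)
        a.SetFormalCharge(int(fc))
        a.SetNoImplicit(True)
        em.AddAtom(a)
    code_to_rd = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                  3.0: Chem.BondType.TRIPLE, AROMATIC_ORDER: Chem.BondType.AROMATIC,
                  AMIDE_ORDER: Chem.BondType.SINGLE}
    for i, j, order in mol.bonds:
        idx = em.AddBond(int(i), int(j),
                         code_to_rd.get(order, Chem.BondType.SINGLE)) - 1
        if order == AROMATIC_ORDER:
            em.GetBondWithIdx(idx).SetIsAromatic(True)
            em.GetAtomWithIdx(int(i)).SetIsAromatic(True)
            em.GetAtomWithIdx(int(j)).SetIsAromatic(True)
    rd = em.GetMol()
    rd.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(rd)
    conf = Chem.Conformer(mol.n_atoms)
    for i, xyz in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    rd.AddConformer(conf, assignId=True)
    rd.SetProp("_Name", mol.name)
    return rd


def _infer_formal_charges(mol: Molecule) -> np.ndarray:
    nbrs = mol.neighbor_lists()
    fcs = np.zeros(mol.n_atoms, dtype=int)
    order_sum = np.zeros(mol.n_atoms)
    for i, j, order in mol.bonds:
        o = 1.5 if order == AROMATIC_ORDER else (1.0 if order == AMIDE_ORDER else order)
        order_sum[i] += o
        order_sum[j] += o
    for i, e in enumerate(mol.elements):
        if e == "N" and len(nbrs[i]) == 4:
            fcs[i] = 1
        elif e == "O" and len(nbrs[i]) == 1 and order_sum[i] == 1.0:
            if not any(mol.elements[j] == "H" for j in nbrs[i]):
                fcs[i] = -1
    return fcs
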