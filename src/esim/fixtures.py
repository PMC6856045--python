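"""Deterministic generation of all test inputs.

Everything is built in code from line notation plus a seeded embedding: the
small-molecule panel used throughout the examples (2-pyrrolidone and its
mimics), multi-conformer ensembles with MMFF94 energies, aligned pairs with
controlled molecular/direct-atomic overlap, and labeled synthetic screening
libraries (actives that preserve the query's polar-feature geometry and
field signs; decoys that are isosteric but have shuffled or neutralized
charge/hydrogen-bond character).  Regeneration with the same seed is
bit-identical.
"""

from __future__ import annotations

import numpy as np

from .chem import (ConformerEnsemble, Molecule, assign_radii_and_charges,
                   from_rdkit, perceive_polar_features)
from .overlap import compute_overlap

#: name -> SMILES for the worked-example panel
PANEL_SMILES: dict[str, str] = {
    "2-pyrrolidone": "O=C1CCCN1",
    "cyclopentanone": "O=C1CCCC1",
    "pyrrole": "c1cc[nH]c1",
    "acetate": "CC(=O)[O-]",
    "acetamidine": "CC(=[NH2+])N",
    "benzene": "c1ccccc1",
    "water": "O",
    "pyridine": "c1ccncc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
}


def prepare(mol: Molecule, charge_model: str = "gasteiger") -> Molecule:
    """Radii + partial charges + polar-feature perception in one step."""
    return perceive_polar_features(assign_radii_and_charges(mol, charge_model))


def molecule_from_smiles(smiles: str, name: str, seed: int = 0,
                         charge_model: str = "gasteiger") -> Molecule:
    """A prepared 3D molecule from line notation: seeded ETKDG embedding,
    MMFF94 (or UFF fallback) minimization, charges, radii, polar features."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if rd is None:
        raise ValueError(f"bad SMILES {smiles!r}")
    ok = AllChem.EmbedMolecule(rd, randomSeed=int(seed) % (2 ** 31 - 1) or 1)
    if ok != 0:
        raise ValueError(f"embedding failed for {smiles!r}")
    if AllChem.MMFFHasAllMoleculeParams(rd):
        AllChem.MMFFOptimizeMolecule(rd)
    else:
        AllChem.UFFOptimizeMolecule(rd)
    mol = from_rdkit(rd, name=name)
    return prepare(mol, charge_model)


def build_panel(seed: int = 0,
                charge_model: str = "gasteiger") -> dict[str, Molecule]:
    """The named worked-example molecules, fully prepared."""
    return {name: molecule_from_smiles(smi, name, seed=seed + k,
                                       charge_model=charge_model)
            for k, (name, smi) in enumerate(PANEL_SMILES.items())}


def build_ensemble(smiles: str, name: str, n_conf: int = 10, seed: int = 0,
                   charge_model: str = "gasteiger") -> ConformerEnsemble:
    """A multi-conformer ensemble with MMFF94 relative energies.

    The ensemble records the absolute minimum energy (``abs_min_energy``)
    so torsional optimization can re-evaluate strain.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.AddHs(Chem.MolFromSmiles(smiles))
    cids = AllChem.EmbedMultipleConfs(
        rd, numConfs=n_conf, randomSeed=int(seed) % (2 ** 31 - 1) or 1)
    if not cids:
        raise ValueError(f"embedding failed for {smiles!r}")
    energies = []
    use_mmff = AllChem.MMFFHasAllMoleculeParams(rd)
    if use_mmff:
        results = AllChem.MMFFOptimizeMoleculeConfs(rd)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(rd)
    energies = np.array([e for _, e in results], dtype=float)
    mol = prepare(from_rdkit(rd, conf_id=int(cids[0]), name=name), charge_model)
    confs = [np.array(rd.GetConformer(int(c)).GetPositions()) for c in cids]
    ens = ConformerEnsemble(mol, confs, energies - energies.min())
    ens.abs_min_energy = float(energies.min())  # type: ignore[attr-defined]
    return ens


# ---------------------------------------------------------------------------
# Overlap pairs
# ---------------------------------------------------------------------------

def build_overlap_pair(target: Molecule, mode: str,
                       seed: int = 0) -> tuple[Molecule, Molecule]:
    """An aligned (target, subject) pair with controlled overlap character.

    ``shared-scaffold`` jitters a copy slightly (high direct atomic overlap);
    ``mimic-no-overlap`` rotates a copy in its least-extended plane so atom
    centers stay inside the target's volume while atom-to-atom overlap is
    destroyed (high MO, low DAO).  The requested property is verified at
    generation time; bounded retries, then an error.
    """
    rng = np.random.default_rng(seed)
    if mode == "shared-scaffold":
        for sigma in (0.15, 0.10, 0.05, 0.02):
            subject = target.copy()
            subject.coords = target.coords + rng.normal(0.0, sigma,
                                                        target.coords.shape)
            subject.name = f"{target.name}-jitter"
            rep = compute_overlap(subject, target)
            if rep.dao >= 0.5:
                return target, subject
        raise RuntimeError("could not build a shared-scaffold pair")
    if mode == "mimic-no-overlap":
        center = target.coords.mean(axis=0)
        cov = np.cov((target.coords - center).T)
        _, vecs = np.linalg.eigh(cov)
        axis = vecs[:, 0]  # least-variance direction: in-plane rotation
        from scipy.spatial.transform import Rotation

        for deg in range(22, 62, 4):
            rot = Rotation.from_rotvec(np.deg2rad(deg) * axis).as_matrix()
            subject = target.copy()
            subject.coords = (target.coords - center) @ rot.T + center
            subject.name = f"{target.name}-mimic"
            rep = compute_overlap(subject, target)
            if rep.mo >= 0.8 and rep.dao < 0.5:
                return target, subject
        raise RuntimeError("could not build a mimic pair for this scaffold")
    raise ValueError(f"unknown overlap-pair mode {mode!r}")


# ---------------------------------------------------------------------------
# Screening libraries
# ---------------------------------------------------------------------------

def _single_conf(mol: Molecule) -> ConformerEnsemble:
    return ConformerEnsemble(mol, [mol.coords.copy()], np.zeros(1))


def build_screen_set(query: Molecule, n_act: int = 20, n_dec: int = 200,
                     seed: int = 0,
                     ) -> tuple[list[ConformerEnsemble], list[int]]:
    """A labeled synthetic screening library around ``query``.

    Actives are near-copies: small coordinate jitter plus sign-preserving
    10% charge noise, so polar-feature geometry and field signs survive.
    Decoys are isosteres in two flavors, half each: ``shuffle`` decoys keep
    the polar features but carry a seeded random permutation of the partial
    charges (wrong field, right hydrogen bonding); ``neutral`` decoys lose
    their donor/acceptor character and have a mildly perturbed field (a
    single heavy-atom charge swap), emulating carbon isosteres.  Every
    molecule is returned in a randomized rigid pose.
    """
    if n_act < 1 or n_dec < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    library: list[ConformerEnsemble] = []
    labels: list[int] = []

    def randomized(mol: Molecule) -> Molecule:
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=rng).as_matrix()
        c = mol.coords.mean(axis=0)
        out = mol.copy()
        out.coords = (mol.coords - c) @ rot.T + c + rng.uniform(-8, 8, 3)
        return out

    for k in range(n_act):
        mol = query.copy()
        mol.name = f"active_{k:03d}"
        mol.coords = query.coords + rng.normal(0.0, 0.08, query.coords.shape)
        mol.charges = query.charges * (1.0 + rng.uniform(-0.1, 0.1,
                                                         query.n_atoms))
        library.append(_single_conf(randomized(mol)))
        labels.append(1)

    heavy_idx = np.flatnonzero(query.heavy_mask)
    for k in range(n_dec):
        mol = query.copy()
        mol.coords = query.coords + rng.normal(0.0, 0.08, query.coords.shape)
        if k % 2 == 0:
            mol.name = f"decoy_shuffle_{k:03d}"
            perm = rng.permutation(query.n_atoms)
            mol.charges = query.charges[perm]
        else:
            mol.name = f"decoy_neutral_{k:03d}"
            i, j = rng.choice(heavy_idx, size=2, replace=False)
            q = query.charges.copy()
            q[i], q[j] = q[j], q[i]
            mol.charges = q
            mol.donors = []
            mol.acceptors = []
        library.append(_single_conf(randomized(mol)))
        labels.append(0)
    return library, labels
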