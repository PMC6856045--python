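"""Observer-point placement and feature evaluation.

Observer points are placed on the ``gamma`` offset surface of an alignment
target (one molecule or several mutually aligned ones): a tessellated sphere
enclosing the target is relaxed radially for ten iterations until every point
sits ``gamma`` from the nearest van der Waals surface, then thinned by
max-min selection to the requested inter-point spacing (2.0 A for geometric
work, 4.0 A for screening).  For multi-molecule targets, points derived from
each constituent ligand individually are appended when they fall more than
2.0 A from the evolving set, so small ligands hidden inside the union still
get surface coverage.

At every observer point, six values characterize any posed molecule:
steric (surface) distance; Coulombic energy of a +0.2 e probe; distance and
angle to the nearest donor proton; distance and angle to the nearest acceptor
atom.  The same module provides the reverse-mode chain rule from per-point
feature sensitivities back to atom coordinates, which powers the analytic
pose gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .chem import Molecule
from .params import ABSENT_DISTANCE, DEFAULT_PARAMS, SimParams

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: augmentation threshold: ligand-specific points further than this from the
#: evolving set are appended (A)
AUGMENT_DISTANCE = 2.0
PROJECTION_ITERATIONS = 10
SPHERE_MARGIN = 8.0          # sphere radius beyond the furthest surface point
TESSELLATION_SPACING = 1.0   # inter-point distance of the initial sphere


@dataclass
class FeatureTable:
    """The six feature values of one posed molecule at every observer point.

    Also carries the argmin bookkeeping (nearest atom / donor / acceptor per
    point) needed for the analytic gradient.  ``don``/``acc`` distances are
    the large ABSENT_DISTANCE sentinel, with angle 0, when the molecule has
    no donors (acceptors); the attention weights then vanish smoothly.
    """

    stc: np.ndarray
    coul: np.ndarray
    don: np.ndarray
    don_theta: np.ndarray
    acc: np.ndarray
    acc_theta: np.ndarray
    stc_atom: np.ndarray
    don_index: np.ndarray
    acc_index: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.stc, self.coul, self.don, self.don_theta,
                                self.acc, self.acc_theta])


@dataclass
class ObserverSet:
    """Placed observer points plus precomputed target features.

    ``tables`` holds one :class:`FeatureTable` per constituent target ligand
    (joint queries score a subject against the per-point maximum over these).
    ``c_t`` is the normalization constant making the target's self-comparison
    score exactly 10; it is filled in by the similarity kernel.
    """

    points: np.ndarray
    gamma: float
    spacing: float
    targets: list[Molecule]
    tables: list[FeatureTable] = field(default_factory=list)
    c_t: float = 0.0
    n_base: int = 0

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def tessellate_sphere(center: np.ndarray, radius: float,
                      target_spacing: float) -> np.ndarray:
    """Deterministic quasi-uniform sphere covering (spherical Fibonacci
    lattice) with nearest-neighbor distance close to ``target_spacing``."""
    if radius <= 0 or target_spacing <= 0:
        raise ValueError("radius and spacing must be positive")
    n = max(8, int(round(4.0 * np.pi * (radius / target_spacing) ** 2)))
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r_xy = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = k * GOLDEN_ANGLE
    pts = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    return np.asarray(center, dtype=float) + radius * pts


def _surface_distances(points: np.ndarray, coords: np.ndarray,
                       radii: np.ndarray) -> np.ndarray:
    """Min over atoms of (distance - vdw radius); shape (n_points,)."""
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    return (d - radii[None, :]).min(axis=1)


def _project_points(points: np.ndarray, centroid: np.ndarray,
                    coords: np.ndarray, radii: np.ndarray,
                    gamma: float) -> np.ndarray:
    """Relax points radially (along the centroid ray) so their min surface
    distance converges to gamma; repeated a fixed number of iterations."""
    pts = points.copy()
    for _ in range(PROJECTION_ITERATIONS):
        dmin = _surface_distances(pts, coords, radii)
        v = pts - centroid
        norms = np.linalg.norm(v, axis=1)
        norms = np.where(norms < 1e-12, 1.0, norms)
        u = v / norms[:, None]
        pts = pts - (dmin - gamma)[:, None] * u
    return pts


def _maxmin_prune(points: np.ndarray, spacing: float) -> np.ndarray:
    """Iterative max-min thinning started from the lowest-index point.

    Repeatedly selects the unselected point whose distance to the nearest
    selected point is maximal, stopping when that distance no longer exceeds
    ``spacing``; ties break toward the lowest index for reproducibility.
    """
    n = points.shape[0]
    if n == 0:
        return points
    selected = [0]
    dmin = np.linalg.norm(points - points[0], axis=1)
    while True:
        i = int(np.argmax(dmin))  # argmax returns the first (lowest) index
        if dmin[i] <= spacing:
            break
        selected.append(i)
        dmin = np.minimum(dmin, np.linalg.norm(points - points[i], axis=1))
    return points[selected]


def _require_radii(mol: Molecule) -> None:
    if mol.radii is None:
        raise ValueError(f"molecule {mol.name!r} has no radii assigned")


def _single_target_points(mols: Sequence[Molecule], gamma: float,
                          spacing: float) -> np.ndarray:
    coords = np.vstack([m.coords for m in mols])
    radii = np.concatenate([m.radii for m in mols])
    centroid = coords.mean(axis=0)
    sphere_r = float(np.max(np.linalg.norm(coords - centroid, axis=1) + radii)
                     + SPHERE_MARGIN)
    pts = tessellate_sphere(centroid, sphere_r, TESSELLATION_SPACING)
    pts = _project_points(pts, centroid, coords, radii, gamma)
    return _maxmin_prune(pts, spacing)


def place_observers(targets: Sequence[Molecule] | Molecule,
                    gamma: float = 4.0, spacing: float = 2.0,
                    params: Optional[SimParams] = None) -> ObserverSet:
    """Build the observer set for a target ligand or aligned ligand set.

    Computes the per-ligand target feature tables at every retained point and
    the self-comparison normalization constant.
    """
    if isinstance(targets, Molecule):
        targets = [targets]
    targets = list(targets)
    if not targets or any(m.n_atoms == 0 for m in targets):
        raise ValueError("target must contain at least one molecule with atoms")
    for m in targets:
        _require_radii(m)
    params = params if params is not None else DEFAULT_PARAMS

    base = _single_target_points(targets, gamma, spacing)
    points = base
    if len(targets) > 1:
        # per-ligand augmentation: guarantees coverage of ligands hidden
        # inside the union's surface
        for mol in targets:
            lig_pts = _single_target_points([mol], gamma, spacing)
            for p in lig_pts:
                if np.min(np.linalg.norm(points - p, axis=1)) > AUGMENT_DISTANCE:
                    points = np.vstack([points, p])
    obs = ObserverSet(points=points, gamma=gamma, spacing=spacing,
                      targets=targets, n_base=base.shape[0])
    obs.tables = [compute_features(m, obs) for m in targets]
    from .kernel import normalize_constant

    obs.c_t = normalize_constant(obs, params)
    return obs


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def steric_distance(mol: Molecule, point: np.ndarray) -> float:
    """Distance from ``point`` to the molecular surface: min over atoms of
    (center distance - vdw radius)."""
    _require_radii(mol)
    d = np.linalg.norm(mol.coords - np.asarray(point, dtype=float), axis=1)
    return float(np.min(d - mol.radii))


def coulombic_energy(mol: Molecule, point: np.ndarray, gamma: float = 4.0,
                     probe_charge: float = DEFAULT_PARAMS.probe_charge,
                     coulomb_constant: float = DEFAULT_PARAMS.coulomb_constant,
                     ) -> float:
    """Coulombic energy (kcal/mol) of the probe charge at ``point``.

    Distances are re-scaled by ``gamma - 2`` so observers feel charges as if
     2 A from the surface, and an unbounded sigmoidal dielectric switches the
    interaction off roughly one water shell beyond ``gamma``.
    """
    if mol.charges is None:
        raise ValueError("molecule has no charges assigned")
    r = np.linalg.norm(mol.coords - np.asarray(point, dtype=float), axis=1)
    return float(_coul_terms(r, mol.charges, gamma, probe_charge,
                             coulomb_constant).sum())


def _coul_terms(r: np.ndarray, q: np.ndarray, gamma: float,
                probe_charge: float, coulomb_constant: float) -> np.ndarray:
    d = np.clip(r - (gamma - 2.0), 0.0, None)
    inv_eps = expit(-(r - (gamma + 2.0)) / 0.5)  # 1/eps in (0, 1]
    return probe_charge * coulomb_constant * q * inv_eps / (d + 0.05)


def donor_feature(mol: Molecule, point: np.ndarray) -> tuple[float, float]:
    """(surface distance, angle) of the nearest donor proton.

    The angle sits at the proton, between the observer and the heavy atom the
    proton is attached to: pi for ideal, linear donor geometry.  Molecules
    with no donors return the absent sentinel (huge distance, angle 0).
    """
    table = compute_features(mol, _point_obs(point))
    return float(table.don[0]), float(table.don_theta[0])


def acceptor_feature(mol: Molecule, point: np.ndarray) -> tuple[float, float]:
    """(surface distance, angle) of the nearest acceptor atom; the angle sits
    at the acceptor, between the observer and the centroid of the acceptor's
    bonded neighbors (pi when the lone pair points at the observer)."""
    table = compute_features(mol, _point_obs(point))
    return float(table.acc[0]), float(table.acc_theta[0])


def _point_obs(point: np.ndarray) -> ObserverSet:
    return ObserverSet(points=np.asarray(point, dtype=float).reshape(1, 3),
                       gamma=4.0, spacing=2.0, targets=[])


def _angles(points: np.ndarray, vertex: np.ndarray,
            third: np.ndarray) -> np.ndarray:
    """Angle at ``vertex[i]`` between ``points[i]`` and ``third[i]``."""
    a = points - vertex
    b = third - vertex
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    cosang = np.einsum("ij,ij->i", a, b) / np.clip(na * nb, 1e-12, None)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def compute_features(mol: Molecule, obs: ObserverSet,
                     params: Optional[SimParams] = None) -> FeatureTable:
    """Evaluate all six feature values at every observer point (vectorized)."""
    _require_radii(mol)
    params = params if params is not None else DEFAULT_PARAMS
    pts = obs.points
    n = pts.shape[0]
    gamma = obs.gamma

    diff = pts[:, None, :] - mol.coords[None, :, :]
    r = np.linalg.norm(diff, axis=2)  # (n_points, n_atoms)
    surf = r - mol.radii[None, :]
    stc_atom = np.argmin(surf, axis=1)
    stc = surf[np.arange(n), stc_atom]

    if mol.charges is not None:
        coul = _coul_terms(r, mol.charges[None, :], gamma,
                           params.probe_charge, params.coulomb_constant).sum(axis=1)
    else:
        coul = np.zeros(n)

    if mol.donors:
        protons = np.array([d.proton for d in mol.donors])
        bases = np.array([d.base for d in mol.donors])
        dsurf = surf[:, protons]
        don_index = np.argmin(dsurf, axis=1)
        don = dsurf[np.arange(n), don_index]
        hpos = mol.coords[protons[don_index]]
        bpos = mol.coords[bases[don_index]]
        don_theta = _angles(pts, hpos, bpos)
    else:
        don = np.full(n, ABSENT_DISTANCE)
        don_theta = np.zeros(n)
        don_index = np.full(n, -1, dtype=int)

    if mol.acceptors:
        acc_atoms = np.array([a.index for a in mol.acceptors])
        asurf = surf[:, acc_atoms]
        acc_index = np.argmin(asurf, axis=1)
        acc = asurf[np.arange(n), acc_index]
        apos = mol.coords[acc_atoms[acc_index]]
        cents = np.array([mol.coords[list(a.neighbors)].mean(axis=0)
                          for a in mol.acceptors])
        acc_theta = _angles(pts, apos, cents[acc_index])
    else:
        acc = np.full(n, ABSENT_DISTANCE)
        acc_theta = np.zeros(n)
        acc_index = np.full(n, -1, dtype=int)

    return FeatureTable(stc=stc, coul=coul, don=don, don_theta=don_theta,
                        acc=acc, acc_theta=acc_theta, stc_atom=stc_atom,
                        don_index=don_index, acc_index=acc_index)


# ---------------------------------------------------------------------------
# Reverse-mode geometry chain rule
# ---------------------------------------------------------------------------

def _angle_grads(points: np.ndarray, vertex: np.ndarray, third: np.ndarray):
    """d(theta)/d(vertex), d(theta)/d(third) for the angle at ``vertex``.

    Singular exactly at 0/pi; the sine is floored, which zeroes the gradient
    smoothly near collinearity.
    """
    a = points - vertex
    b = third - vertex
    na = np.clip(np.linalg.norm(a, axis=1), 1e-12, None)
    nb = np.clip(np.linalg.norm(b, axis=1), 1e-12, None)
    ah = a / na[:, None]
    bh = b / nb[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", ah, bh), -1.0, 1.0)
    sinang = np.clip(np.sqrt(1.0 - cosang ** 2), 1e-8, None)
    dth_da = -(bh - cosang[:, None] * ah) / (na * sinang)[:, None]
    dth_db = -(ah - cosang[:, None] * bh) / (nb * sinang)[:, None]
    dvertex = -(dth_da + dth_db)
    return dvertex, dth_db


def feature_backprop(mol: Molecule, obs: ObserverSet, table: FeatureTable,
                     d_stc: np.ndarray, d_coul: np.ndarray,
                     d_don: np.ndarray, d_dontheta: np.ndarray,
                     d_acc: np.ndarray, d_acctheta: np.ndarray,
                     params: Optional[SimParams] = None) -> np.ndarray:
    """Map per-point feature sensitivities to an atom-coordinate gradient.

    Given d(objective)/d(feature) arrays over observer points, returns
    d(objective)/d(coords), shape (n_atoms, 3).  The argmin selections
    (nearest atom, donor, acceptor) recorded in ``table`` are held fixed, so
    the result is the gradient of the piecewise-smooth objective.
    """
    params = params if params is not None else DEFAULT_PARAMS
    pts = obs.points
    n = pts.shape[0]
    grad = np.zeros_like(mol.coords)

    # steric: stc_i = |p_i - x_j*| - rho_j*
    xj = mol.coords[table.stc_atom]
    v = xj - pts
    rn = np.clip(np.linalg.norm(v, axis=1), 1e-12, None)
    np.add.at(grad, table.stc_atom, (d_stc / rn)[:, None] * v)

    # coulombic: smooth sum over all atoms
    if mol.charges is not None and np.any(d_coul):
        diff = mol.coords[None, :, :] - pts[:, None, :]
        r = np.clip(np.linalg.norm(diff, axis=2), 1e-12, None)
        gamma = obs.gamma
        kq = params.probe_charge * params.coulomb_constant * mol.charges[None, :]
        d = np.clip(r - (gamma - 2.0), 0.0, None)
        z = (r - (gamma + 2.0)) / 0.5
        inv_eps = expit(-z)
        dinv_eps = -inv_eps * (1.0 - inv_eps) / 0.5
        step = (r > (gamma - 2.0)).astype(float)
        dterm_dr = kq * (dinv_eps / (d + 0.05)
                         - inv_eps * step / (d + 0.05) ** 2)
        w = d_coul[:, None] * dterm_dr / r          # (n_points, n_atoms)
        grad += np.einsum("pa,pax->ax", w, diff)

    # donors: distance at the proton, angle at the proton toward the base
    if mol.donors:
        protons = np.array([dn.proton for dn in mol.donors])
        bases = np.array([dn.base for dn in mol.donors])
        hsel = protons[table.don_index]
        bsel = bases[table.don_index]
        hpos = mol.coords[hsel]
        v = hpos - pts
        rn = np.clip(np.linalg.norm(v, axis=1), 1e-12, None)
        np.add.at(grad, hsel, (d_don / rn)[:, None] * v)
        dvert, dthird = _angle_grads(pts, hpos, mol.coords[bsel])
        np.add.at(grad, hsel, d_dontheta[:, None] * dvert)
        np.add.at(grad, bsel, d_dontheta[:, None] * dthird)

    # acceptors: distance at the acceptor, angle toward the neighbor centroid
    if mol.acceptors:
        acc_atoms = np.array([a.index for a in mol.acceptors])
        asel = acc_atoms[table.acc_index]
        apos = mol.coords[asel]
        v = apos - pts
        rn = np.clip(np.linalg.norm(v, axis=1), 1e-12, None)
        np.add.at(grad, asel, (d_acc / rn)[:, None] * v)
        cents = np.array([mol.coords[list(a.neighbors)].mean(axis=0)
                          for a in mol.acceptors])
        dvert, dthird = _angle_grads(pts, apos, cents[table.acc_index])
        np.add.at(grad, asel, d_acctheta[:, None] * dvert)
        for k, a in enumerate(mol.acceptors):
            mask = table.acc_index == k
            if not np.any(mask):
                continue
            share = dthird[mask] / len(a.neighbors)
            contrib = (d_acctheta[mask, None] * share).sum(axis=0)
            for j in a.neighbors:
                grad[j] += contrib
    return grad
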