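"""Pose generation and optimization against an observer set.

Candidate rigid alignments come from matching typed site triangles (ring
centroids, donor protons, acceptor atoms, terminal heavy atoms) between the
subject conformer and the target ligand(s); each compatible triangle pair
yields a least-squares rigid transform.  Candidates are scored, the best few
kept, and each is refined by BFGS on the six rigid parameters (rotation
vector + translation), using the analytic score gradient.  The geometric
mode additionally optimizes rotatable-bond torsions in internal coordinates
and re-evaluates conformer strain with MMFF94 afterwards.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chem import ConformerEnsemble, Molecule
from .kernel import ScoreBreakdown, score_gradient, score_pose
from .observers import ObserverSet
from .params import DEFAULT_PARAMS, SimParams

TRIANGLE_SIDE_TOL = 0.75   # max side-length mismatch for a triangle pair, A
SEED_DEDUP_RMSD = 0.5      # transforms closer than this collapse to one seed
POSE_DEDUP_RMSD = 0.25     # distinct final poses must differ by this much
MAX_SITES = 12             # cap on typed sites per molecule for seeding


@dataclass(frozen=True)
class SearchMode:
    """A speed/accuracy mode: conformer cap, flexibility, search breadth."""

    name: str
    conf_cap: int
    flexible: bool
    seeds_kept: int
    maxiter: int
    gtol: float
    spacing: float  # observer spacing a caller should use with this mode


MODES: dict[str, SearchMode] = {
    "pfast": SearchMode("pfast", 25, False, 10, 40, 1e-3, 4.0),
    "pscreen": SearchMode("pscreen", 120, False, 25, 80, 1e-4, 4.0),
    "pgeom": SearchMode("pgeom", 250, True, 50, 150, 1e-5, 2.0),
}


@dataclass
class Pose:
    """One scored placement of a subject conformer."""

    conformer_index: int
    rotation: np.ndarray
    translation: np.ndarray
    coords: np.ndarray
    score: float
    breakdown: Optional[ScoreBreakdown] = None
    torsions: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coordinates must be finite")


# ---------------------------------------------------------------------------
# Conformer downsampling
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Heavy-lifting-free least-squares superposition RMSD of two
    coordinate sets in identical atom order."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd / np.sqrt(a.shape[0]))


def downsample_ensemble(ens: ConformerEnsemble, cap: int) -> ConformerEnsemble:
    """Greedy max-min diversity selection, seeded with the global-minimum
    conformer; returns the ensemble unchanged if already within the cap."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(ens) <= cap:
        return ens
    start = int(np.argmin(ens.energies))
    selected = [start]
    dmin = np.array([kabsch_rmsd(ens.conformers[start], c)
                     for c in ens.conformers])
    while len(selected) < cap:
        i = int(np.argmax(dmin))
        selected.append(i)
        d_new = np.array([kabsch_rmsd(ens.conformers[i], c)
                          for c in ens.conformers])
        dmin = np.minimum(dmin, d_new)
    return ens.subset(sorted(selected))


# ---------------------------------------------------------------------------
# Triangle seeding
# ---------------------------------------------------------------------------

def _heavy_rings(mol: Molecule) -> list[list[int]]:
    g = nx.Graph()
    heavy = mol.heavy_mask
    g.add_nodes_from(i for i in range(mol.n_atoms) if heavy[i])
    g.add_edges_from((i, j) for i, j, _ in mol.bonds if heavy[i] and heavy[j])
    return nx.minimum_cycle_basis(g)


def match_sites(mol: Molecule) -> list[tuple[str, np.ndarray]]:
    """Typed landmark sites used for triangle matching: heavy-atom ring
    centroids, donor protons, acceptor atoms, terminal heavy atoms."""
    sites: list[tuple[str, np.ndarray]] = []
    for ring in _heavy_rings(mol):
        sites.append(("ring", mol.coords[sorted(ring)].mean(axis=0)))
    for d in mol.donors:
        sites.append(("don", mol.coords[d.proton].copy()))
    for a in mol.acceptors:
        sites.append(("acc", mol.coords[a.index].copy()))
    heavy = mol.heavy_mask
    nbrs = mol.neighbor_lists()
    for i in range(mol.n_atoms):
        if heavy[i] and sum(1 for j in nbrs[i] if heavy[j]) == 1:
            sites.append(("term", mol.coords[i].copy()))
    return sites[:MAX_SITES]


def _kabsch_transform(src: np.ndarray, dst: np.ndarray):
    """Proper rigid transform (R, t) minimizing |R src + t - dst|^2."""
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - dc, src - sc)
    r = rot.as_matrix()
    return r, dc - r @ sc


def _axis_seeds(subject_coords: np.ndarray,
                target_coords: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Centroid/principal-axes fallback: four proper sign combinations."""
    sc = subject_coords.mean(axis=0)
    tc = target_coords.mean(axis=0)

    def axes(x):
        c = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        v = vt.T
        if v.shape[1] < 3:
            v = np.hstack([v, np.zeros((3, 3 - v.shape[1]))])
        if np.linalg.det(v) < 0:
            v[:, 2] *= -1
        return v

    vs, vt_ = axes(subject_coords), axes(target_coords)
    seeds = []
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        flip = np.diag([s1, s2, s1 * s2])  # det +1
        r = vt_ @ flip @ vs.T
        seeds.append((r, tc - r @ sc))
    return seeds


def triangle_seeds(subject: Molecule, obs: ObserverSet,
                   side_tol: float = TRIANGLE_SIDE_TOL
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate rigid transforms from typed-triangle matching.

    Falls back to the four principal-axes placements when either side has
    fewer than three sites or no compatible triangle pair exists.  Both
    triangle orientations are explored through the vertex correspondences.
    """
    s_sites = match_sites(subject)
    t_sites: list[tuple[str, np.ndarray]] = []
    for t in obs.targets:
        t_sites.extend(match_sites(t))
    t_sites = t_sites[:2 * MAX_SITES]
    target_coords = np.vstack([t.coords for t in obs.targets])

    if len(s_sites) < 3 or len(t_sites) < 3:
        return _axis_seeds(subject.coords, target_coords)

    heavy = subject.heavy_mask
    ref = subject.coords[heavy]
    seeds: list[tuple[np.ndarray, np.ndarray]] = []
    placed: list[np.ndarray] = []

    def try_add(r, t):
        moved = ref @ r.T + t
        for prev in placed:
            if np.sqrt(np.mean(np.sum((moved - prev) ** 2, axis=1))) < SEED_DEDUP_RMSD:
                return
        placed.append(moved)
        seeds.append((r, t))

    s_tris = list(itertools.combinations(range(len(s_sites)), 3))
    t_tris = list(itertools.combinations(range(len(t_sites)), 3))
    for si in s_tris:
        s_types = tuple(sorted(s_sites[i][0] for i in si))
        s_pts = np.array([s_sites[i][1] for i in si])
        if _triangle_area(s_pts) < 0.05:
            continue
        for ti in t_tris:
            t_types = tuple(sorted(t_sites[i][0] for i in ti))
            if s_types != t_types:
                continue
            t_pts_all = [t_sites[i] for i in ti]
            if _triangle_area(np.array([p for _, p in t_pts_all])) < 0.05:
                continue
            for perm in itertools.permutations(range(3)):
                if tuple(s_sites[si[k]][0] for k in range(3)) != \
                        tuple(t_pts_all[perm[k]][0] for k in range(3)):
                    continue
                t_pts = np.array([t_pts_all[perm[k]][1] for k in range(3)])
                ok = all(
                    abs(np.linalg.norm(s_pts[a] - s_pts[b])
                        - np.linalg.norm(t_pts[a] - t_pts[b])) <= side_tol
                    for a, b in ((0, 1), (0, 2), (1, 2)))
                if not ok:
                    continue
                r, t = _kabsch_transform(s_pts, t_pts)
                try_add(r, t)
    if not seeds:
        return _axis_seeds(subject.coords, target_coords)
    return seeds


def _triangle_area(pts: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])))


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionDef:
    """A rotatable bond: rotating ``moving`` atoms about axis i->j."""

    i: int
    j: int
    moving: tuple[int, ...]


def rotatable_bonds(mol: Molecule) -> list[TorsionDef]:
    """Acyclic single bonds with a heavy substituent on each side; amide C-N
    bonds excluded."""
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    for i, j, _ in mol.bonds:
        g.add_edge(i, j)
    ring_edges = set()
    for cyc in nx.minimum_cycle_basis(g):
        cs = set(cyc)
        for i, j in g.edges():
            if i in cs and j in cs:
                ring_edges.add(frozenset((i, j)))
    nbrs = mol.neighbor_lists()
    heavy = mol.heavy_mask

    def heavy_subst(a: int, other: int) -> bool:
        return any(heavy[k] for k in nbrs[a] if k != other)

    def is_amide(i: int, j: int) -> bool:
        for a, b in ((i, j), (j, i)):
            if mol.elements[a] == "C" and mol.elements[b] == "N":
                for i2, j2, o in mol.bonds:
                    if o == 2.0 and a in (i2, j2):
                        other = j2 if i2 == a else i2
                        if mol.elements[other] == "O":
                            return True
        return False

    out = []
    for i, j, order in mol.bonds:
        if order not in (1.0,):
            continue
        if frozenset((i, j)) in ring_edges:
            continue
        if not (heavy[i] and heavy[j]):
            continue
        if not (heavy_subst(i, j) and heavy_subst(j, i)):
            continue
        if is_amide(i, j):
            continue
        h = g.copy()
        h.remove_edge(i, j)
        moving = nx.node_connected_component(h, j)
        if len(moving) > mol.n_atoms - len(moving):
            i, j = j, i
            moving = nx.node_connected_component(h, j)
        out.append(TorsionDef(i=i, j=j, moving=tuple(sorted(moving))))
    return out


def apply_torsions(coords: np.ndarray, torsions: Sequence[TorsionDef],
                   deltas: np.ndarray) -> np.ndarray:
    """Rotate each torsion's moving set about its bond axis by delta
    radians, sequentially."""
    x = coords.copy()
    for td, delta in zip(torsions, deltas):
        if abs(delta) < 1e-12:
            continue
        axis = x[td.j] - x[td.i]
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * delta).as_matrix()
        idx = list(td.moving)
        x[idx] = (x[idx] - x[td.i]) @ rot.T + x[td.i]
    return x


# ---------------------------------------------------------------------------
# Rigid parametrization and BFGS refinement
# ---------------------------------------------------------------------------

def _rotvec_jacobian(omega: np.ndarray, r: np.ndarray) -> list[np.ndarray]:
    """dR/d(omega_k) for the rotation-vector parametrization."""
    theta2 = float(omega @ omega)
    eye = np.eye(3)
    if theta2 < 1e-16:
        return [_hat(eye[k]) for k in range(3)]
    hat_w = _hat(omega)
    out = []
    for k in range(3):
        v = omega[k] * hat_w + _hat(np.cross(omega, (eye - r) @ eye[k]))
        out.append(v @ r / theta2)
    return out


def _hat(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def optimize_pose(subject: Molecule, start_coords: np.ndarray,
                  obs: ObserverSet, mode: SearchMode,
                  params: Optional[SimParams] = None,
                  torsions: Optional[Sequence[TorsionDef]] = None
                  ) -> tuple[np.ndarray, Optional[np.ndarray], float, int]:
    """BFGS refinement of a pose from ``start_coords``.

    Optimizes the six rigid parameters (rotation vector about the start
    centroid + translation) and, when ``torsions`` are given, the torsion
    deltas.  Returns (coords, torsion deltas, score without strain,
    iterations); the returned score never falls below the starting one.
    """
    p = params if params is not None else DEFAULT_PARAMS
    torsions = list(torsions) if torsions else []
    n_tor = len(torsions)
    center = start_coords.mean(axis=0)
    best = {"f": np.inf, "x": np.zeros(6 + n_tor)}

    def unpack(xi: np.ndarray):
        omega, t = xi[:3], xi[3:6]
        base = (apply_torsions(start_coords, torsions, xi[6:])
                if n_tor else start_coords)
        r = Rotation.from_rotvec(omega).as_matrix()
        coords = (base - center) @ r.T + center + t
        return coords, base, r, omega

    def objective(xi: np.ndarray):
        coords, base, r, omega = unpack(xi)
        score, g_x = score_gradient(subject.with_coords(coords), obs, p)
        if not np.isfinite(score):
            return 1e9, np.zeros_like(xi)
        grad = np.empty_like(xi)
        grad[3:6] = g_x.sum(axis=0)
        local = base - center
        for k, dr in enumerate(_rotvec_jacobian(omega, r)):
            grad[k] = float(np.sum(g_x * (local @ dr.T)))
        for m, td in enumerate(torsions):
            axis = base[td.j] - base[td.i]
            axis = axis / np.linalg.norm(axis)
            arm = base[list(td.moving)] - base[td.i]
            gen = np.cross(axis, arm) @ r.T
            grad[6 + m] = float(np.sum(g_x[list(td.moving)] * gen))
        if score > -best["f"]:
            best["f"], best["x"] = -score, xi.copy()
        return -score, -grad

    x0 = np.zeros(6 + n_tor)
    res = minimize(objective, x0, jac=True, method="BFGS",
                   options={"maxiter": mode.maxiter, "gtol": mode.gtol})
    xi = best["x"] if best["f"] < res.fun else res.x
    f = min(best["f"], float(res.fun))
    coords, base, r, omega = unpack(xi)
    f0, _ = score_gradient(subject.with_coords(start_coords), obs, p)
    if -f < f0:  # monotone accept: never worse than the start
        return start_coords, (np.zeros(n_tor) if n_tor else None), f0, 0
    return coords, (xi[6:].copy() if n_tor else None), -f, int(res.nit)


# ---------------------------------------------------------------------------
# Full alignment search
# ---------------------------------------------------------------------------

def align(ens: ConformerEnsemble, obs: ObserverSet,
          mode: str | SearchMode = "pscreen", top_n: int = 20,
          params: Optional[SimParams] = None) -> list[Pose]:
    """Pose-predict a subject ensemble against an observer set.

    For every (retained) conformer: generate triangle seeds, score them,
    keep the best few, refine each by BFGS, then return the ``top_n`` final
    poses by score, deduplicated at 0.25 A heavy-atom RMSD.  Deterministic
    for a given input.
    """
    p = params if params is not None else DEFAULT_PARAMS
    m = MODES[mode] if isinstance(mode, str) else mode
    ens = downsample_ensemble(ens, m.conf_cap)
    mol = ens.molecule
    torsions = rotatable_bonds(mol) if m.flexible else None
    heavy = mol.heavy_mask

    poses: list[Pose] = []
    for ci in range(len(ens)):
        conf_mol = ens.molecule_at(ci)
        energy = float(ens.energies[ci])
        seeds = triangle_seeds(conf_mol, obs)
        scored = []
        for k, (r, t) in enumerate(seeds):
            coords = conf_mol.coords @ r.T + t
            bd = score_pose(mol.with_coords(coords), obs, energy, p)
            scored.append((bd.total, k, r, t, coords))
        scored.sort(key=lambda s: (-s[0], s[1]))
        for total0, k, r, t, coords in scored[:m.seeds_kept]:
            opt_coords, tor, raw, nit = optimize_pose(
                mol, coords, obs, m, p, torsions)
            energy_f = energy
            if m.flexible and tor is not None and np.any(np.abs(tor) > 1e-6):
                energy_f = _reevaluate_strain(ens, ci, opt_coords, energy)
            bd = score_pose(mol.with_coords(opt_coords), obs, energy_f, p)
            rot_f, t_f = _net_transform(conf_mol.coords, opt_coords, tor,
                                        torsions, r, t)
            poses.append(Pose(conformer_index=ci, rotation=rot_f,
                              translation=t_f, coords=opt_coords,
                              score=bd.total, breakdown=bd, torsions=tor,
                              provenance={"seed": k, "iterations": nit}))
    poses.sort(key=lambda pz: -pz.score)
    unique: list[Pose] = []
    for pz in poses:
        dup = any(
            pz.conformer_index == u.conformer_index
            and np.sqrt(np.mean(np.sum(
                (pz.coords[heavy] - u.coords[heavy]) ** 2, axis=1)))
            < POSE_DEDUP_RMSD
            for u in unique)
        if not dup:
            unique.append(pz)
        if len(unique) >= top_n:
            break
    return unique


def _net_transform(start: np.ndarray, final: np.ndarray,
                   tor: Optional[np.ndarray],
                   torsions: Optional[Sequence[TorsionDef]],
                   r0: np.ndarray, t0: np.ndarray):
    """Net rigid transform from the seed frame to the final pose."""
    if tor is not None and torsions:
        start = apply_torsions(start, torsions, tor)
    r, t = _kabsch_transform(start, final)
    return r @ r0, r @ t0 + t


def _reevaluate_strain(ens: ConformerEnsemble, ci: int,
                       coords: np.ndarray, fallback: float) -> float:
    """MMFF94 re-evaluation of conformer strain after torsional changes.

    Needs an RDKit handle and the ensemble's absolute minimum energy
    (attached by the fixture builders); otherwise the input-annotated energy
    is kept.
    """
    rd = ens.molecule.rd_mol
    emin = getattr(ens, "abs_min_energy", None)
    if rd is None or emin is None:
        return fallback
    from .forcefield import mmff_energy

    e = mmff_energy(rd, coords)
    if e is None:
        return fallback
    return max(0.0, e - emin)
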