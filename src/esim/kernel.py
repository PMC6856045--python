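"""The similarity function: per-point Gaussian comparisons, attention
weights, normalization, strain, and the joint-query maximum.

A subject pose is compared with the target at every observer point through
Gaussians of the differences in the six feature values.  Donor and acceptor
terms multiply a distance Gaussian, an angle Gaussian, and an attention
weight (a pair of sigmoids) that focuses each observer on polar features
close to it.  Each point is further weighted by how close the *subject*
surface is to the ideal distance gamma, which kills spurious similarity at
points far from a small subject inside a large target's frame.  The total is
normalized so the target's self-comparison scores exactly 10, then reduced
by 0.05 per kcal/mol of subject conformer strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .chem import Molecule, strain_penalty
from .observers import FeatureTable, ObserverSet, compute_features, feature_backprop
from .params import DEFAULT_PARAMS, SimParams

SELF_SCORE = 10.0
SIGMA_OBSERVER = 2.0  # width of the subject-proximity observer weight


def gauss(x, sigma: float):
    """Gaussian kernel ``exp(-x^2 / sigma)`` (sigma is the squared-scale)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-np.square(x) / sigma)


def sigm(x, alpha: float):
    """Logistic sigmoid ``1 / (1 + exp(-x/alpha))``, overflow-safe."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return expit(np.asarray(x, dtype=float) / alpha)


def observer_weight(stc_s, gamma: float):
    """Per-point weight from the subject's surface distance:
    ``g(stc_s - gamma, 2.0)``, maximal when the subject surface sits at the
    ideal observer distance."""
    return gauss(np.asarray(stc_s, dtype=float) - gamma, SIGMA_OBSERVER)


@dataclass
class ScoreBreakdown:
    """Total score and its decomposition.

    ``steric``/``coulombic``/``donor``/``acceptor`` are the observer-weighted,
    component-weighted sums before normalization, so
    ``total = (steric + coulombic + donor + acceptor) / c_t + strain``.
    ``per_point`` has one row per observer point with the four contributions.
    """

    total: float
    steric: float
    coulombic: float
    donor: float
    acceptor: float
    strain: float
    c_t: float
    per_point: np.ndarray = field(repr=False, default=None)


def _attention(dist_s: np.ndarray, dist_t: np.ndarray,
               params: SimParams) -> np.ndarray:
    cutoff = params.gamma + 2.0
    return (sigm(cutoff - dist_s, params.alpha_da)
            + sigm(cutoff - dist_t, params.alpha_da))


def point_similarity(subject: FeatureTable, target: FeatureTable,
                     params: Optional[SimParams] = None) -> np.ndarray:
    """Per-point component similarities; returns (n_points, 4) columns
    steric, coulombic, donor, acceptor."""
    p = params if params is not None else DEFAULT_PARAMS
    s_stc = gauss(subject.stc - target.stc, p.sigma_stc)
    s_coul = gauss(subject.coul - target.coul, p.sigma_coul)
    s_don = (gauss(subject.don - target.don, p.sigma_da)
             * gauss(subject.don_theta - target.don_theta, p.sigma_datheta)
             * _attention(subject.don, target.don, p))
    s_acc = (gauss(subject.acc - target.acc, p.sigma_da)
             * gauss(subject.acc_theta - target.acc_theta, p.sigma_datheta)
             * _attention(subject.acc, target.acc, p))
    return np.column_stack([s_stc, s_coul, s_don, s_acc])


def _weighted_components(subject: FeatureTable, obs: ObserverSet,
                         params: SimParams):
    """Observer-weighted component contributions with the per-point maximum
    over target ligands.  Returns (per_point (n,4), argmax ligand)."""
    w_i = observer_weight(subject.stc, obs.gamma)
    stacks = []
    for table in obs.tables:
        sims = point_similarity(subject, table, params)
        sims[:, 0] *= params.w_shape
        sims[:, 1] *= params.w_coul
        sims[:, 2] *= params.w_da
        sims[:, 3] *= params.w_da
        stacks.append(sims)
    stacked = np.stack(stacks)                      # (n_lig, n_points, 4)
    totals = stacked.sum(axis=2)                    # (n_lig, n_points)
    best = np.argmax(totals, axis=0)                # (n_points,)
    chosen = stacked[best, np.arange(stacked.shape[1])]  # (n_points, 4)
    return w_i[:, None] * chosen, best


def score_pose(subject: Molecule, obs: ObserverSet,
               conf_energy: float = 0.0,
               params: Optional[SimParams] = None) -> ScoreBreakdown:
    """Score a subject molecule pose against an observer set (Eq.-style
    total: normalized weighted sum over points plus the strain term)."""
    p = params if params is not None else DEFAULT_PARAMS
    if abs(p.gamma - obs.gamma) > 1e-12:
        raise ValueError("params.gamma does not match the observer set's gamma")
    if not obs.tables:
        raise ValueError("observer set has no target features")
    if obs.c_t <= 0:
        raise ValueError("observer set has no normalization constant")
    table = compute_features(subject, obs, p)
    per_point, _ = _weighted_components(table, obs, p)
    comp = per_point.sum(axis=0)
    strain = strain_penalty(conf_energy, p.strain_const)
    total = comp.sum() / obs.c_t + strain
    return ScoreBreakdown(total=float(total), steric=float(comp[0]),
                          coulombic=float(comp[1]), donor=float(comp[2]),
                          acceptor=float(comp[3]), strain=float(strain),
                          c_t=obs.c_t, per_point=per_point)


def normalize_constant(obs: ObserverSet, params: Optional[SimParams] = None,
                       joint: str = "mean") -> float:
    """Normalization constant: raw self-comparison sum divided by 10.

    For a joint (multi-ligand) query each constituent is scored as a subject
    under the per-point-maximum semantics; ``joint`` selects the mean of
    those raw self-scores (default) or the first ligand's.
    """
    p = params if params is not None else DEFAULT_PARAMS
    raws = []
    for table in obs.tables:
        per_point, _ = _weighted_components(table, obs, p)
        raws.append(per_point.sum())
        if joint == "first":
            break
    raw = float(np.mean(raws))
    if raw <= 0:
        raise ValueError("degenerate target: zero self-comparison score")
    return raw / SELF_SCORE


def similarity_sticks(breakdown: ScoreBreakdown,
                      obs: ObserverSet) -> pd.DataFrame:
    """Per-observer-point component contributions for visual inspection
    (shape / coulombic / donor / acceptor 'sticks')."""
    if breakdown.per_point is None:
        raise ValueError("breakdown carries no per-point contributions")
    df = pd.DataFrame(obs.points, columns=["x", "y", "z"])
    for k, name in enumerate(["steric", "coulombic", "donor", "acceptor"]):
        df[name] = breakdown.per_point[:, k]
    return df


# ---------------------------------------------------------------------------
# Analytic gradient
# ---------------------------------------------------------------------------

def score_gradient(subject: Molecule, obs: ObserverSet,
                   params: Optional[SimParams] = None
                   ) -> tuple[float, np.ndarray]:
    """Score (without strain) and its gradient w.r.t. subject coordinates.

    Reverse-mode differentiation of the per-point similarity with the argmin
    and per-point-max selections held fixed (the objective is piecewise
    smooth).  Returns (score, (n_atoms, 3) gradient).
    """
    p = params if params is not None else DEFAULT_PARAMS
    table = compute_features(subject, obs, p)
    per_point, best = _weighted_components(table, obs, p)
    total = per_point.sum() / obs.c_t

    n = obs.n_points
    w_i = observer_weight(table.stc, obs.gamma)
    cutoff = p.gamma + 2.0

    # target features of the per-point argmax ligand
    tgt = {name: np.stack([getattr(t, name) for t in obs.tables])
           [best, np.arange(n)]
           for name in ("stc", "coul", "don", "don_theta", "acc", "acc_theta")}

    d_stc_diff = table.stc - tgt["stc"]
    s_stc = gauss(d_stc_diff, p.sigma_stc)
    d_coul_diff = table.coul - tgt["coul"]
    s_coul = gauss(d_coul_diff, p.sigma_coul)

    gd_don = gauss(table.don - tgt["don"], p.sigma_da)
    gt_don = gauss(table.don_theta - tgt["don_theta"], p.sigma_datheta)
    att_don_s = sigm(cutoff - table.don, p.alpha_da)
    att_don = att_don_s + sigm(cutoff - tgt["don"], p.alpha_da)
    s_don = gd_don * gt_don * att_don

    gd_acc = gauss(table.acc - tgt["acc"], p.sigma_da)
    gt_acc = gauss(table.acc_theta - tgt["acc_theta"], p.sigma_datheta)
    att_acc_s = sigm(cutoff - table.acc, p.alpha_da)
    att_acc = att_acc_s + sigm(cutoff - tgt["acc"], p.alpha_da)
    s_acc = gd_acc * gt_acc * att_acc

    inner = (p.w_shape * s_stc + p.w_coul * s_coul
             + p.w_da * (s_don + s_acc))

    # d(total)/d(subject features), all (n_points,)
    dw_dstc = w_i * (-2.0 * (table.stc - obs.gamma) / SIGMA_OBSERVER)
    dg = lambda g, diff, sigma: g * (-2.0 * diff / sigma)  # noqa: E731

    d_stc = (dw_dstc * inner
             + w_i * p.w_shape * dg(s_stc, d_stc_diff, p.sigma_stc))
    d_coul = w_i * p.w_coul * dg(s_coul, d_coul_diff, p.sigma_coul)

    datt_don = -att_don_s * (1.0 - att_don_s) / p.alpha_da
    d_don = w_i * p.w_da * (
        dg(gd_don, table.don - tgt["don"], p.sigma_da) * gt_don * att_don
        + gd_don * gt_don * datt_don)
    d_dontheta = w_i * p.w_da * gd_don * att_don * dg(
        gt_don, table.don_theta - tgt["don_theta"], p.sigma_datheta)

    datt_acc = -att_acc_s * (1.0 - att_acc_s) / p.alpha_da
    d_acc = w_i * p.w_da * (
        dg(gd_acc, table.acc - tgt["acc"], p.sigma_da) * gt_acc * att_acc
        + gd_acc * gt_acc * datt_acc)
    d_acctheta = w_i * p.w_da * gd_acc * att_acc * dg(
        gt_acc, table.acc_theta - tgt["acc_theta"], p.sigma_datheta)

    grad = feature_backprop(subject, obs, table, d_stc, d_coul, d_don,
                            d_dontheta, d_acc, d_acctheta, p)
    return float(total), grad / obs.c_t
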